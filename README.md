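# wbansense

Energy-aware sensor scheduling for wireless body-area-network (WBAN)
health monitoring.

Wearable and implantable sensors can track a patient's health state almost
continuously, but every measurement drains a battery that may be hard to
recharge. `wbansense` implements a controller that decides, at every
decision epoch, **which subset of sensors to activate**, trading the energy
cost of sensing against the risk of misclassifying the patient's health
state.

## The model

The patient's health state `h_t` is a hidden Markov chain over ordered
states `h1 .. hJ` (`h1` least healthy) with transition matrix
`T[i,j] = Pr(h_{t+1}=h_j | h_t=h_i)`. Each of `N` sensors emits a discrete
symbol with state-conditional probabilities `A_n[i,j] = Pr(l_n=i | h_j)`;
deactivated sensors emit nothing. Because the chain is Markov and sensor
outputs are conditionally independent given the state, the posterior
*belief* `b_t(j) = Pr(h_t=h_j | past outputs)` is a sufficient statistic
and updates recursively (predict through `T`, condition on the observed
symbols). The controller therefore solves a Markov decision process on
the belief simplex with stage cost

```
(1 - ω) · C(s)  +  ω · ρ(b)        ρ(b) = Σ_j b_j ρ_j(b)
ρ_j(b) = CFP · Σ_{i<j} b_i  +  CFN · Σ_{i>j} b_i
```

where `C(s)` is the energy cost of the activated subset, `ρ` the expected
misclassification cost of the updated belief, and `ω ∈ [0,1]` weighs the
two. Two controllers are provided:

* **Greedy one-step look-ahead** — activates the subset minimizing the
  immediate expected weighted cost; trivial to run on a microcontroller.
* **Value iteration** — finite-horizon or discounted dynamic programming
  on a discretized belief simplex (grid spacing `1/d`), the near-optimal
  benchmark. Successor beliefs are computed exactly, then snapped to the
  grid; at run time the policy re-minimizes the Bellman right-hand side at
  the actual belief.

An *inclusive* baseline (all sensors always on) bounds the achievable
accuracy. For continuous glucose monitoring (CGM), the package maps a
single physical sensor onto this model by cutting time into `k`-slot
frames: each slot is a virtual sensor, an action is a subset of slots to
measure in, and the collected values are averaged and discretized into the
clinical ranges (≤100, 100–180, >180 mg/dL). Per-patient transition and
emission matrices are estimated from a training portion of the trace.

## Worked example

Compare the three controllers on the built-in three-state / two-sensor
benchmark (sensor energy cost 2 each, `CFP=50`, `CFN=100`, `ω=0.5`,
horizon 50, 200 common-random-number rollouts):

```python
import numpy as np
from wbansense import GreedyPolicy, ValueIterationPolicy, InclusivePolicy, compare_policies
from wbansense.fixtures import compact_instance

inst = compact_instance()
results = compare_policies(
    {"greedy": GreedyPolicy(inst),
     "value_iteration": ValueIterationPolicy(inst, level=15),
     "inclusive": InclusivePolicy(inst)},
    inst, n_epochs=50, n_reps=200, rng=np.random.default_rng(0))
for name, bd in results.items():
    print(f"{name:16s} total={bd.total_cost:7.1f}  energy={bd.activation_cost:6.1f}  "
          f"misclass={bd.misclassification_cost:7.1f}  accuracy={bd.accuracy:.3f}")
```

```
greedy           total=  443.4  energy= 132.7  misclass=  754.1  accuracy=0.854
value_iteration  total=  441.1  energy= 149.7  misclass=  732.6  accuracy=0.860
inclusive        total=  436.9  energy= 200.0  misclass=  673.8  accuracy=0.869
```

`total` is the rollout sum of the weighted stage cost (averaged over
repetitions), `energy` the activation-cost sum, `misclass` the
belief-based misclassification sum, and `accuracy` the fraction of epochs
in which the most likely state equals the true one. On this instance the
greedy controller spends a third less energy than always-on sensing for
~1.5 accuracy points, and sits within about 1% of the dynamic-programming
benchmark's total cost.

The CGM pipeline runs the same comparison on glucose traces (here a
synthetic patient; real exports are read from a
`patient_id,timestamp,glucose_mgdl` CSV):

```python
from wbansense.cgm import synth_trace, fit_and_evaluate
trace = synth_trace(np.random.default_rng(7), n_frames=2000)
for kind in ("inclusive", "greedy"):
    r = fit_and_evaluate(trace, policy=kind)
    print(f"{kind:9s} activation={r.activation_pct:6.2f}%  accuracy={r.breakdown.accuracy:.3f}")
```

```
inclusive activation=100.00%  accuracy=0.986
greedy    activation= 16.67%  accuracy=0.986
```

On clean synthetic glucose, a single measurement per half-hour frame
already matches the always-on accuracy.

A CLI wraps the library: `wbansense simulate|solve|sweep|fit-cgm|synth-cgm|reproduce`
(see `wbansense --help`).

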