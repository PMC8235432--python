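# Methods

This note documents the model implemented by `wbansense`, the estimation
and simulation procedures, the numerical choices, and the limits of what
the synthetic experiments can show.

## Decision model

**Hidden dynamics.** The patient's health state is a finite Markov chain
over ordered states `h1 .. hJ` (index 1 least healthy), with a known,
time-invariant row-stochastic transition matrix `T`. In practice `T` is
estimated from historical data (see the CGM pipeline below); the
controller treats it as fixed.

**Sensing.** Each of `N` sensors is a cheap threshold detector emitting a
symbol from a small alphabet (Λ ≥ 2) with state-conditional probabilities
`A_n` (columns sum to one). Sensor outputs are conditionally independent
given the state — the state is the only coupling, each sensor adds local
noise. An action is an activation vector `s ∈ {0,1}^N` from a
configurable action set; its energy cost is the sum of per-sensor costs
(or an explicit table). A deactivated sensor contributes the neutral
likelihood factor 1.

**Belief filter.** The posterior over states given all past outputs is a
sufficient statistic. One epoch advances it in two steps: prediction
`p = T' b`, then conditioning on the product of the active sensors'
emission likelihoods. An observation with zero probability under the
model raises an error rather than being silently renormalized: in
simulation it cannot occur (observations are sampled from the model), and
on real traces it flags model misfit. The most-likely (MAP) state breaks
ties toward the lower index — the conservative clinical choice.

**Costs.** The stage cost is `(1-ω)·C(s) + ω·ρ`, with `ω ∈ [0,1]`
(default 0.5) weighing energy against misclassification. The
misclassification cost of a belief charges, for each candidate
classification `h_j`, the false-positive unit cost `CFP` on belief mass
at less-healthy states (`i < j`) and the false-negative cost `CFN` on
healthier ones (`i > j`), then averages over the belief itself:
`ρ(b) = Σ_j b_j ρ_j(b)`. A full J×J cost matrix (zero diagonal)
generalizes this; the scalar mode is exactly the matrix with `CFP` above
and `CFN` below the diagonal. The naming convention of the two scalar
costs is ambiguous in parts of the literature (which error is "positive"
depends on whether the scale counts severity up or health up);
`CostModel(swap_roles=True)` exchanges them without touching anything
else. All cost functionals are evaluated on the *updated* one-step-ahead
belief, which is also what rollouts accrue — the realized belief-based
cost, not the 0/1 classification error (accuracy, false-positive and
false-negative rates are reported alongside).

## Policies

**Greedy one-step look-ahead** minimizes the immediate expected weighted
cost, enumerating actions and, per action, the observation distribution
and the resulting posteriors. Ties break by lower activation cost, then
lexicographically smaller activation vector — deterministic and
energy-favoring. Zero-information sensors make the misclassification term
action-independent, so the cheapest action wins.

**Value iteration** approximates the optimal policy on the discretized
belief simplex: all vectors with entries in `{0, 1/d, …, 1}` summing to 1
(`C(d+J-1, J-1)` points). Backward induction (terminal value 0) or
discounted iteration (sup-norm stopping tolerance, contraction-guaranteed)
computes the cost-to-go per grid point; successor beliefs are computed by
the exact Bayes update and then snapped to the L1-nearest grid point
(lexicographically smallest on ties), while stage costs always use the
exact (pre-snap) posteriors. At run time the default policy re-minimizes
the Bellman right-hand side at the *actual* belief, reading only successor
values from the table. This matters: snapping the current belief and
replaying the tabulated argmin ("lookup" mode, also available) inherits
the full grid error at the decision point and can underperform even the
greedy rule at moderate grids (≈14% worse at d=15 with perfect sensors,
where Bellman extraction coincides with greedy exactly, as it should).

**Accurate-sensor special case.** With error-free binary sensors whose
output signatures identify the state uniquely, and an all-or-nothing
action set, every belief either advances deterministically (`T' b`, idle)
or collapses to a pure state (sense). Only `L·(J+1)` beliefs are then
reachable in `L` epochs, and the dynamic program is solved exactly on
that set in `O(L²J)` — no discretization. This provides an internal
correctness oracle for the discretized solver: on a two-state fixture
whose reachable set lies exactly on the d=20 grid (initial belief at the
chain's stationary vector), the two agree to 1e-6.

**Inclusive baseline** activates every sensor at every epoch:
accuracy-optimal, energy-maximal.

## Simulation and evaluation

One epoch proceeds: the policy picks an action from the current belief →
the hidden state makes one transition → active sensors emit symbols
conditioned on the new state → the belief updates → costs accrue
(activation cost of the action; ω-weighted misclassification cost of the
updated belief). Monte-Carlo evaluation vectorizes across repetitions and
uses common random numbers for policy comparisons: the health trajectory
and the full panel of would-be sensor outputs are drawn once per
repetition and shared by all policies — valid because sensing does not
influence the health dynamics. Reported metrics are per-rollout cost sums
averaged over repetitions plus per-epoch accuracy/false-positive/false-
negative fractions (`accuracy + fp + fn = 1`; false positive counts
epochs whose MAP index is below the true index). The accounting identity
`total = (1-ω)·energy + ω·misclassification` holds to 1e-9.

Default experiment scale: horizon 50 epochs, 100 repetitions per
comparison, 30 random transition matrices for the random-dynamics study,
uniform initial belief. The random diagonally dominant generator draws
each diagonal entry uniformly on [0.85, 0.95] and splits the remaining
row mass by a symmetric Dirichlet — persistent dynamics of the same
character as the printed benchmark matrices. These sizes keep every
study reproducible in seconds to minutes on one CPU.

## CGM pipeline

Traces are per-patient `(timestamp, glucose mg/dL)` series. The modal
inter-record gap defines the patient's slot length (records are placed on
the nearest lattice slot; slots swallowed by abnormal gaps stay missing;
a trace with no repeated gap is rejected as degenerate). Slots are
grouped into non-overlapping `k`-slot frames (default `k=6`, i.e. 30-min
decisions at 5-min sampling); frames containing a missing slot are
dropped rather than imputed. The frame's ground-truth state is the
discretized mean of all `k` slots over the clinical ranges `h3 ≤ 100 <
h2 ≤ 180 < h1`.

Each duty-cycling action is a subset of slots (defaults `(4)`, `(2,6)`,
`(1,3,5)`, plus the full frame as the inclusive baseline); the measured
values are averaged and discretized into one symbol, so each action acts
as a single aggregated virtual sensor with its own 3×3 emission matrix.
Estimation uses raw ratios, as one would read them off a contingency
table: transition frequencies between adjacent retained frames (a state
never seen as a source keeps a self-loop — persistence is the
conservative prior) and per-action output frequencies given the frame
state (states never seen get a uniform column). No smoothing is applied
by default.

Evaluation splits each trace chronologically (first 75% train — the
natural split for a monitoring application), fits `T` and the emissions
on the training frames, and replays the chosen policy once,
deterministically, over the test frames using the actually recorded
values. Holes left by dropped frames are bridged by propagating the
belief through the matching power of `T`. A test observation with zero
fitted likelihood is flagged and discarded (the belief keeps its
prediction) — a possibility inherent to raw-ratio estimates, counted and
reported per patient. Activation cost is the number of physically
measured slots; the headline figure is the percentage of the inclusive
policy's activation cost. The value-iteration variant uses discounted
stationary iteration (γ=0.95, tolerance 1e-6, grid level 9) so that the
policy is well-defined for test sequences of any length.

**Synthetic traces.** The generator emulates the *structure* the pipeline
consumes: a frame-level Markov state chain on the wall-clock lattice
(default transition matrix diagonally dominant, with the mid range as the
corridor between hypo- and hyperglycemic excursions), truncated-normal
slot glucose per state (defaults `h1 ~ N(220, 25²)` on (180, 450],
`h2 ~ N(140, 20²)` on (100, 180], `h3 ~ N(85, 10²)` on (40, 100]),
5-minute slots, default 2000 frames per patient, and abnormal time gaps
created by deleting 1–3 consecutive records after a surviving record with
probability 0.169 — so the fraction of records with an abnormal gap
matches the rate by construction. Because slot values are truncated to
their state's range, the aggregated observation always equals the frame
state: the fitted emissions are exactly identity and a single slot per
frame already achieves inclusive-level accuracy. Real CGM data are
noisier at the range boundaries and autocorrelated within frames, so
passing synthetic tests demonstrates correct estimation and control
machinery, not clinical performance; waveform shape, sensor drift,
meal/insulin dynamics and within-frame state changes are deliberately not
modeled.

## Numerical choices

- Probability validation tolerance 1e-9 throughout; belief normalization
  is exact by construction after each update.
- Grid points are enumerated lexicographically, so "first argmin" during
  snapping deterministically yields the lexicographically smallest
  minimizer.
- Terminal value 0 at the horizon; horizon 0 is allowed and returns the
  terminal table.
- Discounted iteration stops when the sup-norm change is ≤ tol (default
  1e-8); the fixed-point residual is bounded by `γ/(1-γ)·tol`.
- Action tie-breaking everywhere: (activation cost, lexicographic
  vector). Exact float ties resolve to the first candidate in that order.
- Observations with zero probability inside the value-iteration stage
  precomputation are masked (probability-zero branches contribute
  nothing); at the filter level they raise.
- Instance serialization round-trips YAML/JSON at full float precision;
  value tables carry the discretization level and an instance fingerprint.

## Known limitations

- Greedy-versus-optimal gaps depend strongly on how persistent the
  dynamics are: on the default diagonally dominant family (diag ∈
  [0.85, 0.95]) the measured plateau advantage of value iteration is
  ≈1%, and it grows sharply toward static dynamics (cost ratio ≈2.7 at a
  fully static chain). Claims about "the" gap are therefore
  family-specific.
- The discretized solver scales as `C(d+J-1, J-1)`·|actions|·|outputs|
  per sweep; it is intended for small J (≤ 5) and modest action sets.
- Time-varying transition or emission models, continuous-output sensors,
  smoothing (backward passes), and per-epoch dynamic costs are out of
  scope.
- The CGM action menu is fixed per run; adaptive frame lengths and
  outlier-aware aggregation are extension hooks, not implemented.
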