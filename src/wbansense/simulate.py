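"""Seeded generative rollouts and Monte-Carlo policy evaluation.

The event order within one epoch follows the controller loop: the policy
picks an activation subset from the current belief, the hidden health state
makes one Markov transition, the active sensors emit symbols conditioned on
the new state, the belief is updated with those symbols, and costs accrue
(the activation cost of the chosen subset plus the expected
misclassification cost of the updated belief).

Policy comparisons use common random numbers: the latent health trajectory
and the full panel of would-be sensor outputs are sampled once per
repetition and shared by all policies, which is valid because the health
dynamics are not influenced by the sensing actions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .belief import INACTIVE, map_state, posterior_from_weights
from .model import (
    BeliefState,
    ProblemInstance,
    SensorModel,
    TransitionModel,
    ValidationError,
)
from .policies import Policy

__all__ = [
    "Trajectory",
    "Rollout",
    "CostBreakdown",
    "sample_trajectory",
    "sample_observation",
    "rollout",
    "evaluate",
    "compare_policies",
]


@dataclass(frozen=True, eq=False)
class Trajectory:
    """Sampled health-state path ``h_0 .. h_E`` (1-based state indices)."""

    states: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", np.asarray(self.states, dtype=int))

    @property
    def n_epochs(self) -> int:
        return self.states.shape[0] - 1


def _sample_categorical_rows(
    probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One draw per row from a (R, K) matrix of row distributions."""
    u = rng.random(probs.shape[0])
    return (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)


def _sample_paths(
    t_mat: np.ndarray,
    start_probs: np.ndarray,
    n_epochs: int,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    states = np.empty((n_reps, n_epochs + 1), dtype=int)
    states[:, 0] = _sample_categorical_rows(
        np.tile(start_probs, (n_reps, 1)), rng
    )
    for t in range(n_epochs):
        states[:, t + 1] = _sample_categorical_rows(t_mat[states[:, t]], rng)
    return states


def sample_trajectory(
    transitions: TransitionModel,
    start: Union[int, BeliefState],
    n_epochs: int,
    rng: np.random.Generator,
) -> Trajectory:
    """Sample ``h_0`` from ``start`` (1-based index or belief), then E steps."""
    if n_epochs < 1:
        raise ValidationError("n_epochs must be >= 1")
    n_states = transitions.n_states
    if isinstance(start, BeliefState):
        start_probs = start.probs
    else:
        start_probs = np.eye(n_states)[int(start) - 1]
    path = _sample_paths(transitions.matrix, start_probs, n_epochs, 1, rng)[0]
    return Trajectory(path + 1)


def sample_observation(
    state: int,
    action: Sequence[int],
    sensors: SensorModel,
    rng: np.random.Generator,
) -> tuple:
    """Each active sensor emits a symbol from its emission column for ``state``."""
    out = []
    for n, active in enumerate(action):
        if not active:
            out.append(INACTIVE)
            continue
        col = sensors.emissions[n][:, int(state) - 1]
        out.append(int((rng.random() > np.cumsum(col)).sum()))
    return tuple(out)


def _sample_panel(
    states: np.ndarray, sensors: SensorModel, rng: np.random.Generator
) -> np.ndarray:
    """Would-be symbols of every sensor at every epoch: (R, E, N) ints.

    Entry (r, t, n) is what sensor n would emit at epoch t+1 given the
    realized state h_{t+1}; policies only reveal the entries of the sensors
    they activate.
    """
    n_reps, cols = states.shape
    n_epochs = cols - 1
    panel = np.empty((n_reps, n_epochs, sensors.n_sensors), dtype=int)
    for n, a in enumerate(sensors.emissions):
        cum = np.cumsum(a, axis=0)  # (Lambda, J)
        for t in range(n_epochs):
            u = rng.random(n_reps)
            panel[:, t, n] = (u[:, None] > cum[:, states[:, t + 1]].T).sum(axis=1)
    return panel


@dataclass(frozen=True, eq=False)
class Rollout:
    """Detailed per-epoch log of one simulated monitoring run."""

    instance: ProblemInstance
    trajectory: Trajectory
    beliefs_before: np.ndarray  # (E, J)
    actions: tuple  # activation vectors, one per epoch
    observations: tuple
    beliefs_after: np.ndarray  # (E, J)
    map_states: np.ndarray  # (E,), 1-based
    activation_costs: np.ndarray  # (E,)
    misclassification_costs: np.ndarray  # (E,)

    @property
    def n_epochs(self) -> int:
        return len(self.actions)

    def to_frame(self) -> pd.DataFrame:
        obs_str = [
            "".join("-" if s is INACTIVE else str(s) for s in o)
            for o in self.observations
        ]
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "true_state": self.trajectory.states[1:],
                "action": ["".join(map(str, a)) for a in self.actions],
                "observation": obs_str,
                "map_state": self.map_states,
                "activation_cost": self.activation_costs,
                "misclassification_cost": self.misclassification_costs,
            }
        )


def rollout(
    policy: Policy,
    instance: ProblemInstance,
    n_epochs: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    trajectory: Optional[Trajectory] = None,
    panel: Optional[np.ndarray] = None,
    initial_belief: Optional[BeliefState] = None,
) -> Rollout:
    """Simulate one closed-loop run and log everything.

    ``trajectory`` and ``panel`` may be supplied for common-random-number
    comparisons; otherwise they are sampled from ``rng``.
    """
    if n_epochs is None:
        n_epochs = instance.horizon
    if trajectory is None:
        if rng is None:
            raise ValidationError("rollout needs an rng when sampling the trajectory")
        trajectory = sample_trajectory(
            instance.transitions, instance.initial_belief, n_epochs, rng
        )
    states0 = trajectory.states - 1
    if panel is None:
        panel = _sample_panel(states0[None, :], instance.sensors, rng)[0]
    b = (initial_belief or instance.initial_belief).probs
    t_mat = instance.transitions.matrix
    cm = instance.cost_matrix()
    before, after, acts, obs_log, maps, act_cost, mis_cost = [], [], [], [], [], [], []
    for t in range(n_epochs):
        before.append(b.copy())
        action = policy.act(BeliefState(b), epoch=t)
        observation = tuple(
            int(panel[t, n]) if active else INACTIVE
            for n, active in enumerate(action)
        )
        weights = np.ones(instance.n_states)
        for n, s in enumerate(observation):
            if s is not INACTIVE:
                weights = weights * instance.sensors.emissions[n][s]
        b = posterior_from_weights(b @ t_mat, weights)
        after.append(b.copy())
        acts.append(action)
        obs_log.append(observation)
        maps.append(map_state(BeliefState(b)))
        act_cost.append(instance.actions.cost(action))
        mis_cost.append(float(b @ (b @ cm)))
    return Rollout(
        instance=instance,
        trajectory=trajectory,
        beliefs_before=np.array(before),
        actions=tuple(acts),
        observations=tuple(obs_log),
        beliefs_after=np.array(after),
        map_states=np.array(maps),
        activation_costs=np.array(act_cost),
        misclassification_costs=np.array(mis_cost),
    )


@dataclass(frozen=True, eq=False)
class CostBreakdown:
    """Monte-Carlo averaged cost and accuracy accounting.

    Cost fields are per-rollout sums averaged over repetitions; the rate
    fields are per-epoch fractions.  ``accuracy + fp_rate + fn_rate = 1``:
    every epoch the most-likely state is either correct, below the true
    index (estimated less healthy than actual: counted as false positive)
    or above it (false negative).
    """

    total_cost: float
    activation_cost: float
    misclassification_cost: float
    accuracy: float
    fp_rate: float
    fn_rate: float
    n_epochs: int
    n_reps: int
    omega: float
    total_cost_se: float = float("nan")
    sensor_activation_rates: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        out = {
            "total_cost": self.total_cost,
            "activation_cost": self.activation_cost,
            "misclassification_cost": self.misclassification_cost,
            "accuracy": self.accuracy,
            "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
            "n_epochs": self.n_epochs,
            "n_reps": self.n_reps,
            "omega": self.omega,
            "total_cost_se": self.total_cost_se,
        }
        if self.sensor_activation_rates is not None:
            out["sensor_activation_rates"] = [
                float(x) for x in self.sensor_activation_rates
            ]
        return out


def _evaluate_on_draws(
    policy: Policy,
    instance: ProblemInstance,
    states: np.ndarray,
    panel: np.ndarray,
) -> CostBreakdown:
    n_reps, cols = states.shape
    n_epochs = cols - 1
    t_mat = instance.transitions.matrix
    cm = instance.cost_matrix()
    omega = instance.omega
    action_matrix = np.array(instance.actions.actions)
    action_costs = np.array(instance.actions.costs)
    emissions = instance.sensors.emissions
    beliefs = np.tile(instance.initial_belief.probs, (n_reps, 1))
    act_sum = np.zeros(n_reps)
    mis_sum = np.zeros(n_reps)
    correct = fp = fn = 0
    sensor_on = np.zeros(instance.n_sensors)
    rows = np.arange(n_reps)
    for t in range(n_epochs):
        a_idx = policy.act_batch(beliefs, epoch=t)
        mask = action_matrix[a_idx]  # (R, N)
        weights = np.ones_like(beliefs)
        for n in range(instance.n_sensors):
            w_n = emissions[n][panel[:, t, n], :]  # (R, J)
            weights = weights * np.where(mask[:, n:n + 1] == 1, w_n, 1.0)
        unnorm = (beliefs @ t_mat) * weights
        norm = unnorm.sum(axis=1, keepdims=True)
        beliefs = unnorm / norm
        act_sum += action_costs[a_idx]
        mis_sum += ((beliefs @ cm) * beliefs).sum(axis=1)
        sensor_on += mask.sum(axis=0)
        map_idx = beliefs.argmax(axis=1)  # first max = lower (less healthy) index
        true_idx = states[:, t + 1]
        correct += int((map_idx == true_idx).sum())
        fp += int((map_idx < true_idx).sum())
        fn += int((map_idx > true_idx).sum())
    totals = (1.0 - omega) * act_sum + omega * mis_sum
    denom = n_reps * n_epochs
    return CostBreakdown(
        total_cost=float(totals.mean()),
        activation_cost=float(act_sum.mean()),
        misclassification_cost=float(mis_sum.mean()),
        accuracy=correct / denom,
        fp_rate=fp / denom,
        fn_rate=fn / denom,
        n_epochs=n_epochs,
        n_reps=n_reps,
        omega=omega,
        total_cost_se=float(totals.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else float("nan"),
        sensor_activation_rates=sensor_on / denom,
    )


def compare_policies(
    policies: Mapping[str, Policy],
    instance: ProblemInstance,
    n_epochs: Optional[int] = None,
    n_reps: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, CostBreakdown]:
    """Evaluate several policies on identical trajectories and sensor draws."""
    if rng is None:
        raise ValidationError("compare_policies needs a seeded generator")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if n_epochs is None:
        n_epochs = instance.horizon
    states = _sample_paths(
        instance.transitions.matrix,
        instance.initial_belief.probs,
        n_epochs,
        n_reps,
        rng,
    )
    panel = _sample_panel(states, instance.sensors, rng)
    return {
        name: _evaluate_on_draws(policy, instance, states, panel)
        for name, policy in policies.items()
    }


def evaluate(
    policy: Policy,
    instance: ProblemInstance,
    n_epochs: Optional[int] = None,
    n_reps: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> CostBreakdown:
    """Monte-Carlo evaluation of a single policy."""
    return compare_policies({"policy": policy}, instance, n_epochs, n_reps, rng)[
        "policy"
    ]
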