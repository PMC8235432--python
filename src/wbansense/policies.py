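"""Sensing policies on the belief-state MDP.

Two families of controllers are provided, plus the always-on baseline:

* the greedy one-step look-ahead policy, which activates the subset of
  sensors minimizing the immediate weighted cost
  ``(1 - omega) * C(s) + omega * E_l[rho(b, l)]``;
* (approximately) optimal policies from dynamic programming on a
  discretized belief simplex — finite-horizon backward induction and
  discounted value iteration — where successor beliefs are computed by the
  exact Bayes update and then snapped to the nearest (L1) grid point;
* the exact dynamic program for the accurate-sensor special case, where
  the reachable belief set is finite (at most ``L * (J + 1)`` states) and
  no discretization is needed.

All tie-breaks are deterministic and energy-favoring: among equal-cost
actions the one with the lower activation cost wins, then the
lexicographically smallest activation vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .belief import emission_product, observation_space
from .model import (
    ActionSet,
    BeliefState,
    ProblemInstance,
    TransitionModel,
    ValidationError,
)

__all__ = [
    "DiscretizedSimplex",
    "ValueTable",
    "enumerate_grid",
    "snap_to_grid",
    "greedy_action",
    "inclusive_action",
    "value_iteration_finite",
    "value_iteration_discounted",
    "reachable_beliefs",
    "exact_dp_accurate",
    "AccurateSolution",
    "Policy",
    "GreedyPolicy",
    "ValueIterationPolicy",
    "InclusivePolicy",
    "FixedActionPolicy",
]


# ---------------------------------------------------------------------------
# discretized simplex
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class DiscretizedSimplex:
    """All belief vectors with entries in {0, 1/d, ..., 1} summing to 1.

    Points are stored lexicographically sorted, which makes "first argmin"
    the lexicographically smallest minimizer during snapping.
    """

    level: int
    points: np.ndarray  # (M, J)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_states(self) -> int:
        return self.points.shape[1]

    def snap_index(self, beliefs: np.ndarray) -> np.ndarray:
        """Indices of the L1-nearest grid points for a (R, J) belief array."""
        arr = np.atleast_2d(np.asarray(beliefs, dtype=float))
        return np.argmin(cdist(arr, self.points, metric="cityblock"), axis=1)


def enumerate_grid(n_states: int, level: int) -> DiscretizedSimplex:
    """Enumerate the compositions of ``level`` into ``n_states`` parts / level."""
    if n_states < 2:
        raise ValidationError("n_states must be >= 2")
    if level < 1:
        raise ValidationError("discretization level must be >= 1")

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first, *rest)

    pts = np.array(list(compositions(level, n_states)), dtype=float) / level
    assert pts.shape[0] == comb(level + n_states - 1, n_states - 1)
    return DiscretizedSimplex(level=level, points=pts)


def snap_to_grid(b: BeliefState, simplex: DiscretizedSimplex) -> np.ndarray:
    """The grid vector minimizing L1 distance to ``b`` (lex-smallest on ties)."""
    vec = np.asarray(b.probs if isinstance(b, BeliefState) else b, dtype=float)
    return simplex.points[int(simplex.snap_index(vec[None, :])[0])]


# ---------------------------------------------------------------------------
# observation channels: shared machinery for greedy and value iteration
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class _Channel:
    """Per-action observation model: likelihood rows W[o, j] = f(l_o, j)."""

    action_index: int
    action: tuple[int, ...]
    cost: float
    weights: np.ndarray  # (n_obs, J)
    observations: tuple


def _build_channels(
    actions: Sequence[tuple[int, ...]],
    costs: Sequence[float],
    weight_matrices: Sequence[np.ndarray],
    observations: Sequence[tuple],
) -> list[_Channel]:
    chans = [
        _Channel(i, tuple(a), float(c), np.asarray(w, dtype=float), tuple(obs))
        for i, (a, c, w, obs) in enumerate(
            zip(actions, costs, weight_matrices, observations)
        )
    ]
    # deterministic tie-break order: (activation cost, lexicographic vector)
    chans.sort(key=lambda ch: (ch.cost, ch.action))
    return chans


@lru_cache(maxsize=64)
def _instance_channels(instance: ProblemInstance) -> tuple[_Channel, ...]:
    weights, obs_lists = [], []
    for action in instance.actions.actions:
        obs = observation_space(action, instance.sensors)
        weights.append(
            np.vstack([emission_product(o, instance.sensors) for o in obs])
        )
        obs_lists.append(obs)
    return tuple(
        _build_channels(
            instance.actions.actions, instance.actions.costs, weights, obs_lists
        )
    )


def _channel_stage_costs(
    predicted: np.ndarray,
    channels: Sequence[_Channel],
    cost_matrix: np.ndarray,
    omega: float,
):
    """Immediate costs and successor data for a batch of predicted beliefs.

    ``predicted`` is (R, J).  Returns, per channel: the (R,) stage cost
    ``(1-omega) C + omega E_l rho``, the (R, n_obs) observation
    probabilities, and the (R, n_obs, J) posteriors (zero rows where the
    observation has probability zero).
    """
    out = []
    for ch in channels:
        pr = predicted @ ch.weights.T  # (R, n_obs)
        un = predicted[:, None, :] * ch.weights[None, :, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            post = np.where(pr[..., None] > 0, un / pr[..., None], 0.0)
        rho = ((post @ cost_matrix) * post).sum(axis=-1)  # (R, n_obs)
        stage = (1.0 - omega) * ch.cost + omega * (pr * rho).sum(axis=-1)
        out.append((stage, pr, post))
    return out


# ---------------------------------------------------------------------------
# greedy and inclusive policies
# ---------------------------------------------------------------------------


def _greedy_indices(
    beliefs: np.ndarray,
    transition: np.ndarray,
    channels: Sequence[_Channel],
    cost_matrix: np.ndarray,
    omega: float,
) -> np.ndarray:
    """Original action indices of the greedy choice for each belief row."""
    predicted = np.atleast_2d(beliefs) @ transition
    stage = np.column_stack(
        [s for s, _, _ in _channel_stage_costs(predicted, channels, cost_matrix, omega)]
    )
    best = np.argmin(stage, axis=1)  # first minimum = tie-break order
    return np.array([channels[k].action_index for k in best])


def greedy_action(b: BeliefState, instance: ProblemInstance) -> tuple[int, ...]:
    """One-step look-ahead action minimizing the immediate weighted cost."""
    return GreedyPolicy(instance).act(b)


def inclusive_action(instance: ProblemInstance) -> tuple[int, ...]:
    """The all-sensors-on action (accuracy-optimal, energy-maximal baseline)."""
    return instance.actions.all_on


class Policy:
    """Deterministic mapping from beliefs (and epoch) to an allowed action."""

    instance: ProblemInstance

    def act_batch(self, beliefs: np.ndarray, epoch: int = 0) -> np.ndarray:
        raise NotImplementedError

    def act(self, b: BeliefState, epoch: int = 0) -> tuple[int, ...]:
        vec = np.asarray(b.probs if isinstance(b, BeliefState) else b, dtype=float)
        idx = int(self.act_batch(vec[None, :], epoch)[0])
        return self.instance.actions.actions[idx]


class GreedyPolicy(Policy):
    def __init__(self, instance: ProblemInstance):
        self.instance = instance
        self._channels = _instance_channels(instance)
        self._cm = instance.cost_matrix()

    def act_batch(self, beliefs: np.ndarray, epoch: int = 0) -> np.ndarray:
        return _greedy_indices(
            beliefs,
            self.instance.transitions.matrix,
            self._channels,
            self._cm,
            self.instance.omega,
        )


class InclusivePolicy(Policy):
    def __init__(self, instance: ProblemInstance):
        self.instance = instance
        self._idx = instance.actions.index(instance.actions.all_on)

    def act_batch(self, beliefs: np.ndarray, epoch: int = 0) -> np.ndarray:
        return np.full(np.atleast_2d(beliefs).shape[0], self._idx, dtype=int)


class FixedActionPolicy(Policy):
    def __init__(self, instance: ProblemInstance, action: Sequence[int]):
        self.instance = instance
        self._idx = instance.actions.index(action)

    def act_batch(self, beliefs: np.ndarray, epoch: int = 0) -> np.ndarray:
        return np.full(np.atleast_2d(beliefs).shape[0], self._idx, dtype=int)


# ---------------------------------------------------------------------------
# value iteration on the discretized simplex
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ValueTable:
    """Dynamic-programming solution on a discretized belief simplex.

    ``values`` holds the cost-to-go per grid point: shape (L+1, M) for a
    finite horizon (epoch 0 first, terminal value last) or (M,) for a
    stationary discounted solution.  ``actions`` holds the argmin action
    index per grid point (per epoch for finite horizon).
    """

    simplex: DiscretizedSimplex
    values: np.ndarray
    actions: np.ndarray
    action_list: tuple[tuple[int, ...], ...]
    stationary: bool
    horizon: Optional[int] = None
    discount: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)) or np.any(self.values < -1e-12):
            raise ValidationError("value table: values must be finite and >= 0")
        if self.actions.size and (
            self.actions.min() < 0 or self.actions.max() >= len(self.action_list)
        ):
            raise ValidationError("value table: action index outside the action set")

    def _epoch_actions(self, epoch: int) -> np.ndarray:
        if self.stationary:
            return self.actions
        return self.actions[min(epoch, self.actions.shape[0] - 1)]

    def action_for(self, b, epoch: int = 0) -> tuple[int, ...]:
        vec = np.asarray(b.probs if isinstance(b, BeliefState) else b, dtype=float)
        idx = int(self.simplex.snap_index(vec[None, :])[0])
        return self.action_list[int(self._epoch_actions(epoch)[idx])]

    def value_at(self, b, epoch: int = 0) -> float:
        vec = np.asarray(b.probs if isinstance(b, BeliefState) else b, dtype=float)
        idx = int(self.simplex.snap_index(vec[None, :])[0])
        vals = self.values if self.stationary else self.values[epoch]
        return float(vals[idx])


def _grid_stage_data(instance: ProblemInstance, simplex: DiscretizedSimplex):
    """Precompute stage costs, observation probabilities and snapped
    successor indices for every (grid point, action) pair."""
    channels = _instance_channels(instance)
    cm = instance.cost_matrix()
    predicted = simplex.points @ instance.transitions.matrix
    stage_cols, prob_cols, succ_cols = [], [], []
    for stage, pr, post in _channel_stage_costs(
        predicted, channels, cm, instance.omega
    ):
        n_pts, n_obs, n_states = post.shape
        succ = simplex.snap_index(post.reshape(-1, n_states)).reshape(n_pts, n_obs)
        stage_cols.append(stage)
        prob_cols.append(pr)
        succ_cols.append(succ)
    return channels, stage_cols, prob_cols, succ_cols


def value_iteration_finite(
    instance: ProblemInstance, simplex: DiscretizedSimplex
) -> ValueTable:
    """Backward induction over the horizon with terminal value zero.

    Successor beliefs are computed by the exact Bayes update and snapped to
    the grid; stage costs are evaluated on the exact (pre-snap) posteriors.
    """
    horizon = instance.horizon
    if horizon < 0:
        raise ValidationError("horizon must be nonnegative")
    if simplex.n_points == 0:
        raise ValidationError("empty belief grid")
    channels, stage, prob, succ = _grid_stage_data(instance, simplex)
    n_pts = simplex.n_points
    values = np.zeros((horizon + 1, n_pts))
    actions = np.zeros((horizon, n_pts), dtype=int)
    for t in range(horizon - 1, -1, -1):
        totals = np.column_stack(
            [
                stage[a] + (prob[a] * values[t + 1][succ[a]]).sum(axis=1)
                for a in range(len(channels))
            ]
        )
        best = np.argmin(totals, axis=1)
        values[t] = totals[np.arange(n_pts), best]
        actions[t] = [channels[k].action_index for k in best]
    return ValueTable(
        simplex=simplex,
        values=values,
        actions=actions,
        action_list=instance.actions.actions,
        stationary=False,
        horizon=horizon,
    )


def value_iteration_discounted(
    instance: ProblemInstance,
    simplex: DiscretizedSimplex,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> ValueTable:
    """Stationary discounted value iteration; converges by contraction."""
    gamma = instance.discount
    if gamma is None or not 0.0 < gamma < 1.0:
        raise ValidationError("discount factor must be set and inside (0, 1)")
    channels, stage, prob, succ = _grid_stage_data(instance, simplex)
    n_pts = simplex.n_points
    values = np.zeros(n_pts)
    for _ in range(max_iter):
        totals = np.column_stack(
            [
                stage[a] + gamma * (prob[a] * values[succ[a]]).sum(axis=1)
                for a in range(len(channels))
            ]
        )
        best = np.argmin(totals, axis=1)
        new = totals[np.arange(n_pts), best]
        delta = np.max(np.abs(new - values))
        values = new
        if delta <= tol:
            break
    actions = np.array([channels[k].action_index for k in best])
    return ValueTable(
        simplex=simplex,
        values=values,
        actions=actions,
        action_list=instance.actions.actions,
        stationary=True,
        discount=gamma,
    )


class ValueIterationPolicy(Policy):
    """Controller backed by the dynamic-programming value table.

    The default ``extraction="bellman"`` re-minimizes the dynamic-programming
    right-hand side at the *actual* belief, using the tabulated cost-to-go
    only for the (grid-snapped) successor beliefs — the standard way to act
    on an approximate value function, and the one that collapses to the
    optimal policy when sensors are perfect.  ``extraction="lookup"`` snaps
    the belief itself to the grid and replays the precomputed argmin there.
    """

    def __init__(
        self,
        instance: ProblemInstance,
        table: Optional[ValueTable] = None,
        level: int = 15,
        extraction: str = "bellman",
    ):
        self.instance = instance
        if table is None:
            simplex = enumerate_grid(instance.n_states, level)
            if instance.discount is not None:
                table = value_iteration_discounted(instance, simplex)
            else:
                table = value_iteration_finite(instance, simplex)
        self.table = table
        if extraction not in ("bellman", "lookup"):
            raise ValidationError("extraction must be 'bellman' or 'lookup'")
        self.extraction = extraction
        self._channels = _instance_channels(instance)
        self._cm = instance.cost_matrix()

    def _continuation(self, epoch: int) -> tuple[np.ndarray, float]:
        """Cost-to-go used for successors of epoch ``epoch``, and its weight."""
        if self.table.stationary:
            return self.table.values, float(self.table.discount)
        nxt = min(epoch + 1, self.table.values.shape[0] - 1)
        return self.table.values[nxt], 1.0

    def act_batch(self, beliefs: np.ndarray, epoch: int = 0) -> np.ndarray:
        beliefs = np.atleast_2d(beliefs)
        if self.extraction == "lookup":
            idx = self.table.simplex.snap_index(beliefs)
            return self.table._epoch_actions(epoch)[idx]
        cont, weight = self._continuation(epoch)
        omega = self.instance.omega
        predicted = beliefs @ self.instance.transitions.matrix
        totals = []
        for stage, pr, post in _channel_stage_costs(
            predicted, self._channels, self._cm, omega
        ):
            n_rows, n_obs, n_states = post.shape
            succ = self.table.simplex.snap_index(
                post.reshape(-1, n_states)
            ).reshape(n_rows, n_obs)
            totals.append(stage + weight * (pr * cont[succ]).sum(axis=1))
        best = np.argmin(np.column_stack(totals), axis=1)
        return np.array([self._channels[k].action_index for k in best])


# ---------------------------------------------------------------------------
# accurate-sensor special case: finite reachable set and exact DP
# ---------------------------------------------------------------------------


class AssumptionError(ValueError):
    """The accurate-sensor assumptions do not hold for this instance."""


def _check_accurate(instance: ProblemInstance) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Verify the accurate-sensor assumptions; return (idle, all-on) actions."""
    n = instance.n_sensors
    idle, full = (0,) * n, (1,) * n
    if set(instance.actions.actions) != {idle, full}:
        raise AssumptionError("action set must be exactly {all-off, all-on}")
    det = instance.sensors.detection_probs  # raises unless binary
    if not np.all(np.isin(det, (0.0, 1.0))):
        raise AssumptionError("sensor output probabilities must all be 0 or 1")
    cols = {tuple(det[:, j]) for j in range(det.shape[1])}
    if len(cols) != det.shape[1]:
        raise AssumptionError(
            "output signatures must identify the state uniquely (distinct columns)"
        )
    return idle, full


def reachable_beliefs(
    instance: ProblemInstance, b0: Optional[BeliefState] = None
) -> list[np.ndarray]:
    """Beliefs reachable within the horizon under accurate sensors.

    With all-or-nothing accurate sensing, every belief either advances
    deterministically to ``T' b`` (idle) or collapses to a pure state
    (sense), so at epochs 1..L only ``T'^m b0`` (m = 1..L) and ``T'^m e_j``
    (m = 0..L-1) occur: at most ``L * (J + 1)`` beliefs.
    """
    _check_accurate(instance)
    if b0 is None:
        b0 = instance.initial_belief
    t_mat = instance.transitions.matrix
    horizon, n_states = instance.horizon, instance.n_states
    seen: dict[tuple, np.ndarray] = {}

    def add(vec: np.ndarray) -> None:
        seen.setdefault(tuple(np.round(vec, 12)), vec)

    vec = np.asarray(b0.probs, dtype=float)
    for _ in range(horizon):
        vec = vec @ t_mat
        add(vec)
    for j in range(n_states):
        vec = np.eye(n_states)[j]
        add(vec)
        for _ in range(horizon - 1):
            vec = vec @ t_mat
            add(vec)
    out = list(seen.values())
    assert len(out) <= horizon * (n_states + 1)
    return out


@dataclass(frozen=True, eq=False)
class AccurateSolution:
    """Exact DP solution over the finite reachable belief set.

    ``values[t]`` maps a rounded belief tuple to its optimal cost-to-go at
    epoch ``t``; ``actions[t]`` maps it to the optimal activation vector.
    """

    values: tuple[dict, ...]
    actions: tuple[dict, ...]
    initial_belief: np.ndarray

    @staticmethod
    def key(belief) -> tuple:
        vec = np.asarray(
            belief.probs if isinstance(belief, BeliefState) else belief, dtype=float
        )
        return tuple(np.round(vec, 12))

    def value_at(self, belief, epoch: int = 0) -> float:
        return self.values[epoch][self.key(belief)]

    def action_for(self, belief, epoch: int = 0) -> tuple[int, ...]:
        return self.actions[epoch][self.key(belief)]

    @property
    def optimal_value(self) -> float:
        return self.value_at(self.initial_belief, 0)


def exact_dp_accurate(
    instance: ProblemInstance, b0: Optional[BeliefState] = None
) -> AccurateSolution:
    """Exact backward induction exploiting the two-successor structure.

    From any belief ``b`` the idle action leads deterministically to
    ``T' b`` (stage cost ``omega * rho(T' b)``), while sensing collapses the
    belief to the realized pure state (stage cost the weighted activation
    cost, with zero misclassification).  Complexity O(L^2 J).
    """
    idle, full = _check_accurate(instance)
    if b0 is None:
        b0 = instance.initial_belief
    t_mat = instance.transitions.matrix
    cm = instance.cost_matrix()
    omega = instance.omega
    horizon, n_states = instance.horizon, instance.n_states
    sense_cost = (1.0 - omega) * instance.actions.cost(full)
    idle_cost = (1.0 - omega) * instance.actions.cost(idle)

    # anchors: index -1 = b0, j = pure state e_{j+1}; belief = anchor @ T^m
    anchors = {-1: np.asarray(b0.probs, dtype=float)}
    for j in range(n_states):
        anchors[j] = np.eye(n_states)[j]

    from functools import lru_cache as _cache

    @_cache(maxsize=None)
    def chain(anchor: int, m: int) -> tuple:
        vec = anchors[anchor]
        for _ in range(m):
            vec = vec @ t_mat
        return tuple(vec)

    @_cache(maxsize=None)
    def solve(t: int, anchor: int, m: int) -> tuple[float, tuple[int, ...]]:
        if t >= horizon:
            return 0.0, idle
        b = np.asarray(chain(anchor, m))
        nxt = b @ t_mat
        rho_idle = float(nxt @ (nxt @ cm))
        v_idle = idle_cost + omega * rho_idle + solve(t + 1, anchor, m + 1)[0]
        v_sense = sense_cost + sum(
            p * solve(t + 1, j, 0)[0] for j, p in enumerate(nxt) if p > 0
        )
        # tie-break: lower activation cost, then lexicographic vector
        if v_sense < v_idle or (
            v_sense == v_idle and (sense_cost, full) < (idle_cost, idle)
        ):
            return v_sense, full
        return v_idle, idle

    values: list[dict] = [dict() for _ in range(horizon + 1)]
    actions: list[dict] = [dict() for _ in range(horizon)]
    # populate every node reachable at each epoch
    frontier = {(-1, 0)}
    for t in range(horizon + 1):
        for anchor, m in frontier:
            key = tuple(np.round(chain(anchor, m), 12))
            if t < horizon:
                v, a = solve(t, anchor, m)
                values[t].setdefault(key, v)
                actions[t].setdefault(key, a)
            else:
                values[t].setdefault(key, 0.0)
        frontier = {(a, m + 1) for a, m in frontier} | {
            (j, 0) for j in range(n_states)
        }
    return AccurateSolution(
        values=tuple(values),
        actions=tuple(actions),
        initial_belief=np.asarray(b0.probs, dtype=float),
    )
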