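"""Domain types for the belief-state health-sensing controller.

A monitoring problem is described by a finite ordered set of patient health
states (index 1 = least healthy), a Markov transition matrix between them,
a bank of discrete-output sensors with per-state emission probabilities,
an action set of sensor-activation subsets with energy costs, and a
misclassification cost structure.  ``ProblemInstance`` bundles all of these
together with a planning horizon and an initial belief.

All matrices are stored as numpy arrays.  State indices exposed through the
public API are 1-based (``h1 .. hJ``); internal array storage is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ATOL",
    "ValidationError",
    "HealthStateSpace",
    "TransitionModel",
    "SensorModel",
    "ActionSet",
    "CostModel",
    "BeliefState",
    "ProblemInstance",
    "validate_instance",
    "make_epsilon_sensors",
    "make_stability_transition",
    "sample_diagonal_dominant_transition",
]

#: absolute tolerance for probability normalisation checks
ATOL = 1e-9


class ValidationError(ValueError):
    """A component of a problem instance violates a structural invariant."""


def _freeze(arr: np.ndarray) -> np.ndarray:
    arr = np.array(arr, dtype=float, copy=True)
    arr.setflags(write=False)
    return arr


# ---------------------------------------------------------------------------
# component types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class HealthStateSpace:
    """Ordered health states ``h1 .. hJ``; index 1 is the least healthy."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @classmethod
    def of_size(cls, n_states: int) -> "HealthStateSpace":
        return cls(tuple(f"h{j}" for j in range(1, n_states + 1)))

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def validate(self) -> None:
        if self.n_states < 2:
            raise ValidationError("states: need at least 2 health states")
        if len(set(self.labels)) != self.n_states:
            raise ValidationError("states: labels must be unique")


@dataclass(frozen=True, eq=False)
class TransitionModel:
    """Row-stochastic matrix T with ``T[i, j] = Pr(h_{t+1}=h_{j+1} | h_t=h_{i+1})``."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", _freeze(self.matrix))

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def validate(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError(f"transitions: matrix must be square, got {m.shape}")
        if np.any(m < 0) or np.any(m > 1):
            raise ValidationError("transitions: entries must lie in [0, 1]")
        rows = m.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=ATOL, rtol=0):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValidationError(
                f"transitions: row {bad + 1} sums to {rows[bad]:.12g}, expected 1"
            )


@dataclass(frozen=True, eq=False)
class SensorModel:
    """Bank of N discrete sensors over J states.

    ``emissions[n]`` is the Lambda x J output-probability matrix of sensor
    ``n``: entry ``(i, j)`` is Pr(output ``i`` | state ``h_{j+1}``).  Columns
    sum to one.  For binary sensors the compact N x J "detection" form holds
    only Pr(output "1" | state); row ``1 - p`` completes each matrix.
    """

    emissions: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "emissions", tuple(_freeze(a) for a in self.emissions))

    @classmethod
    def from_detection_probs(cls, detection: np.ndarray) -> "SensorModel":
        """Build binary sensors from an N x J matrix of Pr(output "1" | state)."""
        det = np.asarray(detection, dtype=float)
        if det.ndim != 2:
            raise ValidationError("sensors: detection matrix must be 2-d (N x J)")
        return cls(tuple(np.vstack([1.0 - row, row]) for row in det))

    @property
    def n_sensors(self) -> int:
        return len(self.emissions)

    @property
    def n_states(self) -> int:
        return self.emissions[0].shape[1]

    @property
    def alphabet_size(self) -> int:
        return self.emissions[0].shape[0]

    @property
    def detection_probs(self) -> np.ndarray:
        """Compact N x J form (binary sensors only): Pr(output "1" | state)."""
        if self.alphabet_size != 2:
            raise ValidationError("sensors: compact form requires a binary alphabet")
        return np.vstack([a[1] for a in self.emissions])

    def validate(self) -> None:
        if not self.emissions:
            raise ValidationError("sensors: need at least one sensor")
        lam, n_states = self.emissions[0].shape
        if lam < 2:
            raise ValidationError("sensors: output alphabet must have size >= 2")
        for n, a in enumerate(self.emissions, start=1):
            if a.shape != (lam, n_states):
                raise ValidationError(
                    f"sensors: sensor {n} has shape {a.shape}, expected {(lam, n_states)}"
                )
            if np.any(a < 0) or np.any(a > 1):
                raise ValidationError(f"sensors: sensor {n} has entries outside [0, 1]")
            cols = a.sum(axis=0)
            if not np.allclose(cols, 1.0, atol=ATOL, rtol=0):
                bad = int(np.argmax(np.abs(cols - 1.0)))
                raise ValidationError(
                    f"sensors: sensor {n} column {bad + 1} sums to {cols[bad]:.12g}"
                )


@dataclass(frozen=True, eq=False)
class ActionSet:
    """Activation subsets ``s in {0,1}^N`` with nonnegative energy costs."""

    actions: tuple[tuple[int, ...], ...]
    costs: tuple[float, ...]
    #: per-sensor costs if the set was built from them (informational)
    sensor_costs: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "actions", tuple(tuple(int(x) for x in a) for a in self.actions)
        )
        object.__setattr__(self, "costs", tuple(float(c) for c in self.costs))
        if self.sensor_costs is not None:
            object.__setattr__(
                self, "sensor_costs", tuple(float(c) for c in self.sensor_costs)
            )

    @classmethod
    def from_sensor_costs(
        cls,
        sensor_costs: Sequence[float],
        actions: Optional[Iterable[Sequence[int]]] = None,
    ) -> "ActionSet":
        """Cost of an action = sum of the active sensors' costs.

        ``actions`` defaults to all 2^N activation subsets (lexicographic).
        """
        cs = np.asarray(sensor_costs, dtype=float)
        if actions is None:
            actions = product((0, 1), repeat=len(cs))
        acts = tuple(tuple(int(x) for x in a) for a in actions)
        costs = tuple(float(np.dot(a, cs)) for a in acts)
        return cls(acts, costs, sensor_costs=tuple(cs))

    @property
    def n_sensors(self) -> int:
        return len(self.actions[0])

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    def index(self, action: Sequence[int]) -> int:
        try:
            return self.actions.index(tuple(int(x) for x in action))
        except ValueError:
            raise ValidationError(f"actions: {tuple(action)} not in the action set") from None

    def cost(self, action: Sequence[int]) -> float:
        return self.costs[self.index(action)]

    @property
    def all_on(self) -> tuple[int, ...]:
        full = (1,) * self.n_sensors
        if full not in self.actions:
            raise ValidationError("actions: all-active action absent from action set")
        return full

    def validate(self) -> None:
        if not self.actions:
            raise ValidationError("actions: action set is empty")
        n = len(self.actions[0])
        if any(len(a) != n for a in self.actions):
            raise ValidationError("actions: activation vectors have inconsistent length")
        if any(x not in (0, 1) for a in self.actions for x in a):
            raise ValidationError("actions: activation vectors must be 0/1")
        if len(set(self.actions)) != len(self.actions):
            raise ValidationError("actions: duplicate activation vectors")
        if len(self.costs) != len(self.actions):
            raise ValidationError("actions: one cost per action required")
        if any(c < 0 for c in self.costs):
            raise ValidationError("actions: negative activation cost")
        if self.sensor_costs is not None:
            idle = (0,) * n
            if idle in self.actions and self.cost(idle) != 0.0:
                raise ValidationError("actions: idle action must cost 0 when built from Cs")


@dataclass(frozen=True, eq=False)
class CostModel:
    """Misclassification cost structure and the energy/accuracy weight omega.

    Scalar mode uses constant false-positive / false-negative unit costs;
    matrix mode uses an explicit J x J matrix whose (i, j) entry is the cost
    of classifying true state ``h_{i+1}`` as ``h_{j+1}`` (zero diagonal).
    The scalar mode is the special case with CFP above and CFN below the
    diagonal of that matrix (so that the per-state cost of classifying as
    ``h_j`` charges CFP for mass on less-healthy states ``i < j`` and CFN on
    healthier states ``i > j``).  ``swap_roles=True`` exchanges the two
    scalar costs, for users preferring the opposite naming convention.
    """

    false_positive: Optional[float] = None
    false_negative: Optional[float] = None
    matrix: Optional[np.ndarray] = None
    weight: float = 0.5
    swap_roles: bool = False

    def __post_init__(self) -> None:
        if self.matrix is not None:
            object.__setattr__(self, "matrix", _freeze(self.matrix))

    def cost_matrix(self, n_states: int) -> np.ndarray:
        """Realized J x J misclassification-cost matrix."""
        if self.matrix is not None:
            return np.asarray(self.matrix)
        if self.false_positive is None or self.false_negative is None:
            raise ValidationError("costs: need either CFP and CFN or a full cost matrix")
        cfp, cfn = self.false_positive, self.false_negative
        if self.swap_roles:
            cfp, cfn = cfn, cfp
        i, j = np.indices((n_states, n_states))
        return np.where(i < j, cfp, np.where(i > j, cfn, 0.0))

    def validate(self, n_states: Optional[int] = None) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValidationError(f"costs: weight omega={self.weight} outside [0, 1]")
        if self.matrix is None:
            if self.false_positive is None or self.false_negative is None:
                raise ValidationError("costs: missing CFP/CFN and no cost matrix")
            if self.false_positive < 0 or self.false_negative < 0:
                raise ValidationError("costs: CFP and CFN must be nonnegative")
        else:
            m = self.matrix
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValidationError("costs: cost matrix must be square")
            if n_states is not None and m.shape[0] != n_states:
                raise ValidationError(
                    f"costs: cost matrix is {m.shape[0]}x{m.shape[0]}, expected {n_states}"
                )
            if np.any(np.diag(m) != 0):
                raise ValidationError("costs: cost-matrix diagonal must be zero")
            if np.any(m < 0):
                raise ValidationError("costs: negative misclassification cost")


@dataclass(frozen=True, eq=False)
class BeliefState:
    """Probability vector over health states: ``probs[j-1] = Pr(h_t = h_j | past)``."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", _freeze(np.atleast_1d(self.probs)))

    @classmethod
    def uniform(cls, n_states: int) -> "BeliefState":
        return cls(np.full(n_states, 1.0 / n_states))

    @classmethod
    def pure(cls, state: int, n_states: int) -> "BeliefState":
        """Degenerate belief on 1-based state index ``state``."""
        b = np.zeros(n_states)
        b[state - 1] = 1.0
        return cls(b)

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    def validate(self) -> None:
        b = self.probs
        if b.ndim != 1:
            raise ValidationError("belief: must be a 1-d probability vector")
        if np.any(b < 0):
            raise ValidationError("belief: negative entry")
        if abs(b.sum() - 1.0) > ATOL:
            raise ValidationError(f"belief: entries sum to {b.sum():.12g}, expected 1")


@dataclass(frozen=True, eq=False)
class ProblemInstance:
    """A complete sensing-control problem."""

    states: HealthStateSpace
    transitions: TransitionModel
    sensors: SensorModel
    actions: ActionSet
    costs: CostModel
    horizon: int = 50
    initial_belief: Optional[BeliefState] = None
    discount: Optional[float] = None

    def __post_init__(self) -> None:
        if self.initial_belief is None:
            object.__setattr__(
                self, "initial_belief", BeliefState.uniform(self.states.n_states)
            )

    @property
    def n_states(self) -> int:
        return self.states.n_states

    @property
    def n_sensors(self) -> int:
        return self.sensors.n_sensors

    @property
    def omega(self) -> float:
        return self.costs.weight

    def cost_matrix(self) -> np.ndarray:
        return self.costs.cost_matrix(self.n_states)


def validate_instance(instance: ProblemInstance) -> ProblemInstance:
    """Check every structural invariant; return the instance if all hold."""
    instance.states.validate()
    instance.transitions.validate()
    instance.sensors.validate()
    instance.actions.validate()
    n_states = instance.states.n_states
    instance.costs.validate(n_states)
    if instance.transitions.n_states != n_states:
        raise ValidationError(
            f"transitions: matrix is {instance.transitions.n_states}-state, "
            f"instance has {n_states} states"
        )
    if instance.sensors.n_states != n_states:
        raise ValidationError(
            f"sensors: emission matrices cover {instance.sensors.n_states} states, "
            f"instance has {n_states}"
        )
    if instance.actions.n_sensors != instance.sensors.n_sensors:
        raise ValidationError(
            f"actions: activation vectors have length {instance.actions.n_sensors}, "
            f"instance has {instance.sensors.n_sensors} sensors"
        )
    if instance.horizon < 0:
        raise ValidationError("horizon: must be nonnegative")
    if instance.discount is not None and not 0.0 < instance.discount < 1.0:
        raise ValidationError(f"discount: {instance.discount} outside (0, 1)")
    instance.initial_belief.validate()
    if instance.initial_belief.n_states != n_states:
        raise ValidationError("initial_belief: wrong dimension")
    return instance


# ---------------------------------------------------------------------------
# parametric constructors
# ---------------------------------------------------------------------------


def make_epsilon_sensors(epsilon: float) -> SensorModel:
    """Two binary sensors over three states with noise parameter epsilon.

    Sensor 1 fires for state h1 and sensor 2 for h2, each with hit
    probability ``1 - epsilon`` and false-alarm probability ``epsilon``:
    detection rows ``(1-e, e, e)`` and ``(e, 1-e, e)``.  ``epsilon = 0``
    gives perfect detectors, ``epsilon = 0.5`` gives zero-information ones.
    """
    if not 0.0 <= epsilon <= 0.5:
        raise ValidationError(f"epsilon={epsilon} outside [0, 0.5]")
    e = float(epsilon)
    det = np.array([[1 - e, e, e], [e, 1 - e, e]])
    return SensorModel.from_detection_probs(det)


def make_stability_transition(stay_prob: float, n_states: int) -> TransitionModel:
    """Symmetric transition matrix with diagonal ``stay_prob``.

    Off-diagonal mass is split evenly, so each row sums to one.  At
    ``stay_prob = 1/J`` the matrix is uniform (dynamics carry no
    information); at ``stay_prob = 1`` the health state is static.
    """
    if not 0.0 <= stay_prob <= 1.0:
        raise ValidationError(f"stay_prob={stay_prob} outside [0, 1]")
    if n_states < 2:
        raise ValidationError("n_states must be >= 2")
    off = (1.0 - stay_prob) / (n_states - 1)
    m = np.full((n_states, n_states), off)
    np.fill_diagonal(m, stay_prob)
    return TransitionModel(m)


def sample_diagonal_dominant_transition(
    n_states: int,
    rng: np.random.Generator,
    diag_low: float = 0.85,
    diag_high: float = 0.95,
) -> TransitionModel:
    """Random row-stochastic matrix whose diagonal dominates every row.

    Each diagonal entry is drawn uniformly on ``[diag_low, diag_high]`` and
    the remaining row mass is split by a symmetric Dirichlet draw, emulating
    health dynamics in which remaining in a state is much likelier than
    transitioning.  Reproducible from the supplied generator.
    """
    if n_states < 2:
        raise ValidationError("n_states must be >= 2")
    if not 0.5 < diag_low <= diag_high <= 1.0:
        raise ValidationError("diagonal sampling interval must lie in (0.5, 1]")
    m = np.zeros((n_states, n_states))
    for i in range(n_states):
        d = rng.uniform(diag_low, diag_high)
        rest = rng.dirichlet(np.ones(n_states - 1)) * (1.0 - d)
        row = np.insert(rest, i, d)
        m[i] = row
    return TransitionModel(m)
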