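"""Continuous-glucose-monitoring pipeline: discretize, frame, fit, evaluate.

A CGM device records glucose roughly every five minutes.  To duty-cycle it
with the belief-state controller, the time line is cut into decision frames
of ``k`` consecutive slots; each slot acts as a *virtual sensor*, and an
action is a subset of slots in which the physical sensor actually measures.
The measurements collected in a frame are averaged and discretized into one
of three clinical glucose ranges, which serve both as the hidden health
states and as the observation alphabet:

* ``h1`` (least healthy): glucose above 180 mg/dL (hyperglycemia),
* ``h2``: 100-180 mg/dL,
* ``h3``: at most 100 mg/dL.

Per patient the pipeline estimates the frame-level transition matrix and a
3x3 emission matrix per action from the training portion of the trace (raw
transition / output ratios, no smoothing), then replays a sensing policy
over the held-out frames using the actually recorded glucose values.

A synthetic trace generator stands in for real CGM exports: frame-level
Markov states with diagonally dominant transitions, truncated-normal slot
glucose per state, 5-minute slots, and occasional abnormal time gaps.  It
is labelled synthetic throughout and does not attempt to reproduce
physiological waveform shape, only the range/occupancy structure the
pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .belief import ImpossibleEvidenceError
from .model import (
    ActionSet,
    BeliefState,
    CostModel,
    HealthStateSpace,
    ProblemInstance,
    SensorModel,
    TransitionModel,
    ValidationError,
    validate_instance,
)
from .policies import FixedActionPolicy, GreedyPolicy, Policy, ValueIterationPolicy
from .simulate import CostBreakdown

__all__ = [
    "GlucoseTrace",
    "SlottedSeries",
    "Frame",
    "FrameSeries",
    "FittedInstance",
    "CgmConfig",
    "CgmReport",
    "DegenerateTraceError",
    "glucose_to_state",
    "regularize",
    "build_frames",
    "frame_observation",
    "estimate_T",
    "estimate_emissions",
    "fit_instance",
    "fit_and_evaluate",
    "synth_trace",
    "DEFAULT_SYNTH_T",
    "DEFAULT_STATE_GLUCOSE",
]

N_CGM_STATES = 3


class DegenerateTraceError(ValueError):
    """The trace has no usable modal sampling interval."""


@dataclass(frozen=True, eq=False)
class GlucoseTrace:
    """Per-patient time-stamped glucose series (mg/dL)."""

    patient_id: str
    timestamps: pd.DatetimeIndex
    glucose: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamps", pd.DatetimeIndex(self.timestamps))
        object.__setattr__(
            self, "glucose", np.asarray(self.glucose, dtype=float)
        )
        if len(self.timestamps) != len(self.glucose):
            raise ValidationError("trace: timestamps and glucose lengths differ")
        if len(self.timestamps) >= 2 and not self.timestamps.is_monotonic_increasing:
            raise ValidationError("trace: timestamps must be strictly increasing")
        if np.any(self.glucose <= 0):
            raise ValidationError("trace: glucose values must be positive")

    def __len__(self) -> int:
        return len(self.glucose)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "timestamp": self.timestamps,
                "glucose_mgdl": self.glucose,
            }
        )


@dataclass(frozen=True, eq=False)
class SlottedSeries:
    """A trace re-indexed on its modal sampling lattice (NaN = missing slot)."""

    patient_id: str
    start: pd.Timestamp
    modal_gap: pd.Timedelta
    values: np.ndarray  # (n_slots,), NaN where no record landed

    @property
    def n_slots(self) -> int:
        return self.values.shape[0]

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())


@dataclass(frozen=True, eq=False)
class Frame:
    """One decision frame: k recorded slot values plus its ground truth."""

    index: int  # position on the frame lattice (gaps leave holes)
    values: np.ndarray  # (k,)
    state: int  # 1-based ground-truth state of the frame
    slot_states: tuple[int, ...]


@dataclass(frozen=True, eq=False)
class FrameSeries:
    k: int
    frames: tuple[Frame, ...]
    modal_gap: pd.Timedelta
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.frames)

    def states(self) -> np.ndarray:
        return np.array([f.state for f in self.frames])


def glucose_to_state(value: float) -> int:
    """Map a glucose value (mg/dL) to its clinical range state (1-based).

    ``<= 100`` is h3, ``100 < v <= 180`` is h2, ``> 180`` is h1.
    """
    v = float(value)
    if not np.isfinite(v) or v <= 0:
        raise ValidationError(f"glucose value must be positive, got {value}")
    if v <= 100.0:
        return 3
    if v <= 180.0:
        return 2
    return 1


def regularize(trace: GlucoseTrace) -> SlottedSeries:
    """Re-index a trace on a uniform lattice at its modal sampling gap.

    The modal inter-record gap becomes the slot length; each record is
    placed on the nearest lattice slot and every slot swallowed by an
    abnormal gap (deviation beyond 50% of the modal gap) stays missing.
    """
    if len(trace) < 2:
        raise DegenerateTraceError("need at least 2 records to find a sampling gap")
    gaps = pd.Series(trace.timestamps).diff().dropna()
    counts = gaps.round("1s").value_counts()
    if int(counts.iloc[0]) <= 1:
        raise DegenerateTraceError("all inter-record gaps are distinct")
    modal = counts.index[counts == counts.iloc[0]].min()
    offsets = (trace.timestamps - trace.timestamps[0]) / modal
    slots = np.round(offsets).astype(int)
    values = np.full(int(slots[-1]) + 1, np.nan)
    for slot, value in zip(slots, trace.glucose):
        if np.isnan(values[slot]):
            values[slot] = value
    return SlottedSeries(
        patient_id=trace.patient_id,
        start=trace.timestamps[0],
        modal_gap=modal,
        values=values,
    )


def build_frames(series: SlottedSeries, k: int = 6) -> FrameSeries:
    """Group slots into consecutive k-slot frames, dropping incomplete ones.

    The frame ground-truth state is the discretized mean of all k slot
    values; frames containing any missing slot are dropped (leaving a hole
    in the frame index).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    n_frames = series.n_slots // k
    if n_frames < 1:
        raise ValidationError(f"series has {series.n_slots} slots, fewer than k={k}")
    frames: list[Frame] = []
    dropped = 0
    for i in range(n_frames):
        chunk = series.values[i * k : (i + 1) * k]
        if np.any(np.isnan(chunk)):
            dropped += 1
            continue
        frames.append(
            Frame(
                index=i,
                values=chunk.copy(),
                state=glucose_to_state(float(chunk.mean())),
                slot_states=tuple(glucose_to_state(v) for v in chunk),
            )
        )
    return FrameSeries(
        k=k, frames=tuple(frames), modal_gap=series.modal_gap, n_dropped=dropped
    )


def frame_observation(frame: Frame, action: Sequence[int]) -> int:
    """Aggregate the slots named by ``action`` (1-based) into one symbol.

    The collected values are averaged and discretized with the clinical
    ranges, yielding a symbol in {1, 2, 3} (state-shaped).
    """
    slots = tuple(int(s) for s in action)
    if not slots:
        raise ValidationError("action must name at least one slot")
    if any(s < 1 or s > len(frame.values) for s in slots):
        raise ValidationError(f"action {slots} indexes outside the frame's {len(frame.values)} slots")
    vals = frame.values[[s - 1 for s in slots]]
    if np.any(np.isnan(vals)):
        raise ValidationError(f"action {slots} indexes a missing slot")
    return glucose_to_state(float(vals.mean()))


def estimate_T(frames: FrameSeries) -> TransitionModel:
    """Empirical frame-state transition frequencies (raw ratios).

    Only adjacent retained frames count; a state never seen as a source
    keeps a self-loop row (persistence is the conservative prior).
    """
    if len(frames) < 2:
        raise ValidationError("need at least 2 frames to estimate transitions")
    counts = np.zeros((N_CGM_STATES, N_CGM_STATES))
    for prev, cur in zip(frames.frames[:-1], frames.frames[1:]):
        if cur.index == prev.index + 1:
            counts[prev.state - 1, cur.state - 1] += 1
    matrix = np.eye(N_CGM_STATES)
    for i in range(N_CGM_STATES):
        total = counts[i].sum()
        if total > 0:
            matrix[i] = counts[i] / total
    return TransitionModel(matrix)


def estimate_emissions(
    frames: FrameSeries, actions: Sequence[Sequence[int]]
) -> tuple[np.ndarray, ...]:
    """Per-action 3x3 emission matrices from raw output ratios.

    Entry (l-1, j-1) of matrix ``a`` is the fraction of frames with ground
    truth ``h_j`` whose aggregated observation under action ``a`` was
    symbol ``l``; states never observed get a uniform column.
    """
    if len(frames) == 0:
        raise ValidationError("no training frames")
    out = []
    for action in actions:
        counts = np.zeros((N_CGM_STATES, N_CGM_STATES))
        for frame in frames.frames:
            symbol = frame_observation(frame, action)
            counts[symbol - 1, frame.state - 1] += 1
        matrix = np.empty_like(counts)
        for j in range(N_CGM_STATES):
            total = counts[:, j].sum()
            matrix[:, j] = counts[:, j] / total if total > 0 else 1.0 / N_CGM_STATES
        out.append(matrix)
    return tuple(out)


# ---------------------------------------------------------------------------
# fitting and policy evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class CgmConfig:
    """Pipeline settings.

    ``actions`` are the duty-cycling slot subsets the controller may pick
    (1-based slot indices within a frame); the full frame is appended
    automatically as the inclusive baseline.  ``omega`` weighs energy
    against misclassification; activation cost of an action is its slot
    count.
    """

    k: int = 6
    actions: tuple[tuple[int, ...], ...] = ((4,), (2, 6), (1, 3, 5))
    cfp: float = 50.0
    cfn: float = 100.0
    omega: float = 0.5
    train_frac: float = 0.75
    discretization: int = 9
    vi_discount: float = 0.95
    vi_tol: float = 1e-6

    @property
    def full_action(self) -> tuple[int, ...]:
        return tuple(range(1, self.k + 1))


@dataclass(frozen=True, eq=False)
class FittedInstance:
    """A ProblemInstance whose parameters were estimated from frames.

    Each duty-cycling action is encoded as a virtual aggregated sensor
    (3-symbol alphabet, one 3x3 emission matrix) activated alone; the
    activation vector of action ``a`` is the unit vector ``e_a`` and its
    energy cost is the number of physical measurement slots.
    """

    instance: ProblemInstance
    slot_actions: tuple[tuple[int, ...], ...]
    full_index: Optional[int]

    def restricted(self) -> "FittedInstance":
        """Drop the full-frame action (the duty-cycling controller's menu)."""
        if self.full_index is None:
            return self
        keep = [i for i in range(len(self.slot_actions)) if i != self.full_index]
        inst = self.instance
        n = len(self.slot_actions)
        actions = ActionSet(
            actions=tuple(inst.actions.actions[i] for i in keep),
            costs=tuple(inst.actions.costs[i] for i in keep),
        )
        sub = ProblemInstance(
            states=inst.states,
            transitions=inst.transitions,
            sensors=inst.sensors,
            actions=actions,
            costs=inst.costs,
            horizon=inst.horizon,
            initial_belief=inst.initial_belief,
            discount=inst.discount,
        )
        return FittedInstance(
            instance=validate_instance(sub),
            slot_actions=tuple(self.slot_actions[i] for i in keep),
            full_index=None,
        )

    def action_slots(self, activation: Sequence[int]) -> tuple[int, ...]:
        return self.slot_actions[list(activation).index(1)]


def fit_instance(
    frames: FrameSeries, config: Optional[CgmConfig] = None, horizon: int = 50
) -> FittedInstance:
    """Estimate T and per-action emissions and assemble the decision model."""
    config = config or CgmConfig()
    slot_actions = tuple(tuple(a) for a in config.actions)
    full = config.full_action
    full_index: Optional[int] = None
    if full not in slot_actions:
        slot_actions = slot_actions + (full,)
    full_index = slot_actions.index(full)
    transitions = estimate_T(frames)
    emissions = estimate_emissions(frames, slot_actions)
    n_act = len(slot_actions)
    activation_vectors = tuple(
        tuple(1 if j == i else 0 for j in range(n_act)) for i in range(n_act)
    )
    instance = ProblemInstance(
        states=HealthStateSpace(("h1", "h2", "h3")),
        transitions=transitions,
        sensors=SensorModel(emissions),
        actions=ActionSet(
            actions=activation_vectors,
            costs=tuple(float(len(a)) for a in slot_actions),
        ),
        costs=CostModel(
            false_positive=config.cfp, false_negative=config.cfn, weight=config.omega
        ),
        horizon=horizon,
        discount=config.vi_discount,
    )
    return FittedInstance(
        instance=validate_instance(instance),
        slot_actions=slot_actions,
        full_index=full_index,
    )


@dataclass(frozen=True, eq=False)
class CgmReport:
    """Outcome of replaying one policy over a patient's test frames."""

    patient_id: str
    policy: str
    breakdown: CostBreakdown
    activation_pct: float  # percent of the inclusive policy's activation cost
    n_train: int
    n_test: int
    n_flagged: int  # test frames whose observation had zero model likelihood
    fitted: FittedInstance
    frame_log: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "policy": self.policy,
            "activation_pct": self.activation_pct,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_flagged": self.n_flagged,
            **self.breakdown.to_dict(),
        }


def _make_policy(kind: str, fitted: FittedInstance, config: CgmConfig) -> tuple[Policy, FittedInstance]:
    if kind == "inclusive":
        if fitted.full_index is None:
            raise ValidationError("inclusive policy needs the full-frame action")
        vec = fitted.instance.actions.actions[fitted.full_index]
        return FixedActionPolicy(fitted.instance, vec), fitted
    restricted = fitted.restricted()
    if kind == "greedy":
        return GreedyPolicy(restricted.instance), restricted
    if kind == "vi":
        return (
            ValueIterationPolicy(restricted.instance, level=config.discretization),
            restricted,
        )
    raise ValidationError(f"unknown policy kind {kind!r}; use greedy, vi or inclusive")


def fit_and_evaluate(
    trace: GlucoseTrace,
    policy: str = "greedy",
    config: Optional[CgmConfig] = None,
) -> CgmReport:
    """Chronological 75/25 train/test split, fit, and single-pass replay.

    The chosen policy runs over the test frames using the actually recorded
    slot values; holes left by dropped frames are bridged by propagating
    the belief through the corresponding power of the fitted transition
    matrix.  Observations with zero likelihood under the fitted model are
    flagged and discarded (the belief keeps its prediction) rather than
    renormalized.
    """
    config = config or CgmConfig()
    series = build_frames(regularize(trace), config.k)
    n_total = len(series)
    n_train = int(np.floor(config.train_frac * n_total))
    if n_train < 2 or n_total - n_train < 1:
        raise ValidationError(
            f"insufficient data: {n_total} frames cannot support a "
            f"{config.train_frac:.0%} train split"
        )
    train = FrameSeries(
        k=series.k, frames=series.frames[:n_train], modal_gap=series.modal_gap
    )
    test_frames = series.frames[n_train:]
    fitted = fit_instance(train, config)
    pol, pol_fitted = _make_policy(policy, fitted, config)

    t_mat = fitted.instance.transitions.matrix
    cm = fitted.instance.cost_matrix()
    omega = config.omega
    belief = np.full(N_CGM_STATES, 1.0 / N_CGM_STATES)
    prev_index: Optional[int] = None
    rows = []
    act_sum = mis_sum = 0.0
    correct = fp = fn = flagged = 0
    for frame in test_frames:
        delta = 1 if prev_index is None else frame.index - prev_index
        # idle through the (delta - 1) unobserved frames
        for _ in range(delta - 1):
            belief = belief @ t_mat
        activation = pol.act(BeliefState(belief))
        slots = pol_fitted.action_slots(activation)
        symbol = frame_observation(frame, slots)
        sensor_idx = pol_fitted.slot_actions.index(slots)
        weights = fitted.instance.sensors.emissions[sensor_idx][symbol - 1]
        predicted = belief @ t_mat
        unnorm = predicted * weights
        norm = unnorm.sum()
        if norm <= 0.0:
            flagged += 1
            belief = predicted
        else:
            belief = unnorm / norm
        rho = float(belief @ (belief @ cm))
        act_sum += len(slots)
        mis_sum += rho
        map_state_idx = int(belief.argmax()) + 1
        correct += map_state_idx == frame.state
        fp += map_state_idx < frame.state
        fn += map_state_idx > frame.state
        rows.append(
            {
                "frame_index": frame.index,
                "true_state": frame.state,
                "slots": "".join(map(str, slots)),
                "observation": symbol,
                "map_state": map_state_idx,
                "activation_cost": len(slots),
                "misclassification_cost": rho,
            }
        )
        prev_index = frame.index
    n_test = len(test_frames)
    breakdown = CostBreakdown(
        total_cost=(1.0 - omega) * act_sum + omega * mis_sum,
        activation_cost=act_sum,
        misclassification_cost=mis_sum,
        accuracy=correct / n_test,
        fp_rate=fp / n_test,
        fn_rate=fn / n_test,
        n_epochs=n_test,
        n_reps=1,
        omega=omega,
    )
    return CgmReport(
        patient_id=trace.patient_id,
        policy=policy,
        breakdown=breakdown,
        activation_pct=100.0 * act_sum / (config.k * n_test),
        n_train=n_train,
        n_test=n_test,
        n_flagged=flagged,
        fitted=fitted,
        frame_log=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# synthetic trace generation
# ---------------------------------------------------------------------------

#: default frame-level transition matrix for synthetic patients:
#: diagonally dominant, with the mid range (h2) acting as the corridor
#: between hypo- and hyperglycemic excursions.
DEFAULT_SYNTH_T = np.array(
    [
        [0.86, 0.12, 0.02],
        [0.05, 0.90, 0.05],
        [0.02, 0.12, 0.86],
    ]
)

#: per-state glucose distributions: mean, sd, truncation range (mg/dL)
DEFAULT_STATE_GLUCOSE: dict[int, tuple[float, float, tuple[float, float]]] = {
    1: (220.0, 25.0, (180.0, 450.0)),
    2: (140.0, 20.0, (100.0, 180.0)),
    3: (85.0, 10.0, (40.0, 100.0)),
}


def synth_trace(
    rng: np.random.Generator,
    transitions: Optional[TransitionModel] = None,
    state_glucose: Optional[dict] = None,
    n_frames: int = 2000,
    anomaly_rate: float = 0.169,
    k: int = 6,
    slot_minutes: int = 5,
    patient_id: str = "synthetic-001",
    start: str = "2008-01-01 00:00",
) -> GlucoseTrace:
    """Generate a synthetic CGM trace with the structure real exports show.

    The hidden state follows the frame-level Markov chain on the wall-clock
    lattice; every slot of a frame draws glucose from the state's truncated
    normal.  Abnormal gaps are then injected by deleting short runs of
    records: after any surviving record, with probability ``anomaly_rate``
    the next 1-3 records are dropped, so that the fraction of records with
    an abnormal time gap matches ``anomaly_rate``.
    """
    if transitions is None:
        transitions = TransitionModel(DEFAULT_SYNTH_T)
    transitions.validate()
    if transitions.n_states != N_CGM_STATES:
        raise ValidationError("synthetic generator needs a 3-state transition matrix")
    if not 0.0 <= anomaly_rate < 1.0:
        raise ValidationError("anomaly_rate must lie in [0, 1)")
    state_glucose = state_glucose or DEFAULT_STATE_GLUCOSE
    t_mat = transitions.matrix

    # frame-level state chain (start from the chain's uniform prior)
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.integers(N_CGM_STATES)
    u = rng.random(n_frames - 1)
    cum = np.cumsum(t_mat, axis=1)
    for i in range(1, n_frames):
        states[i] = (u[i - 1] > cum[states[i - 1]]).sum()

    n_slots = n_frames * k
    slot_states = np.repeat(states, k)
    values = np.empty(n_slots)
    for s in range(N_CGM_STATES):
        idx = slot_states == s
        mean, sd, (lo, hi) = state_glucose[s + 1]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        values[idx] = stats.truncnorm.rvs(
            a, b, loc=mean, scale=sd, size=int(idx.sum()), random_state=rng
        )

    keep = np.ones(n_slots, dtype=bool)
    pos = 0
    while pos < n_slots - 1:
        if rng.random() < anomaly_rate:
            run = int(rng.integers(1, 4))  # delete 1-3 records => gap of 2-4 slots
            keep[pos + 1 : pos + 1 + run] = False
            pos += run + 1
        else:
            pos += 1
    times = pd.date_range(
        start=start, periods=n_slots, freq=pd.Timedelta(minutes=slot_minutes)
    )
    return GlucoseTrace(
        patient_id=patient_id,
        timestamps=times[keep],
        glucose=values[keep],
    )
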