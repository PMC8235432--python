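"""Experiment runners: policy comparisons, sensitivity sweeps, cohorts.

Every runner is a plain function returning pandas DataFrames (one row per
sweep point / policy) plus a summary dict; randomness is derived from a
single integer seed through ``numpy.random.SeedSequence`` so that reruns
with the same configuration reproduce results bit for bit.  Policy
comparisons use common random numbers: all policies at a sweep point see
identical health trajectories and sensor draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import cgm
from .fixtures import (
    compact_instance,
    epsilon_instance,
    four_state_instance,
    stability_instance,
)
from .model import (
    TransitionModel,
    ValidationError,
    sample_diagonal_dominant_transition,
)
from .policies import GreedyPolicy, InclusivePolicy, Policy, ValueIterationPolicy
from .simulate import compare_policies, evaluate, rollout

__all__ = [
    "ExperimentConfig",
    "discretization_experiment",
    "epsilon_experiment",
    "stability_experiment",
    "cgm_omega_experiment",
    "cgm_frame_length_experiment",
    "synthetic_cohort",
    "cgm_policy_table",
    "reproduce_fixture",
    "run_sweep",
    "DEFAULT_GRIDS",
]

DEFAULT_GRIDS = {
    "discretization": (3, 5, 7, 9, 11, 13, 15, 17, 20),
    "epsilon": tuple(np.round(np.arange(0.0, 0.301, 0.05), 2)),
    "stability": tuple(np.round(np.arange(0.3, 1.001, 0.05), 2)),
    "omega": tuple(np.round(np.arange(0.1, 0.91, 0.1), 1)),
    "k": (4, 6, 8, 12),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved settings of one sweep run (written next to its results)."""

    sweep: str
    grid: tuple
    seed: int
    reps: int = 100
    horizon: int = 50
    n_matrices: int = 30
    level: int = 15
    n_frames: int = 2000

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValidationError("sweep grid must be nonempty")
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = [float(g) if not float(g).is_integer() else int(g) for g in self.grid]
        return d


# ---------------------------------------------------------------------------
# synthetic-benchmark sweeps
# ---------------------------------------------------------------------------


def discretization_experiment(
    seed: int,
    levels: Sequence[int] = DEFAULT_GRIDS["discretization"],
    n_matrices: int = 30,
    reps: int = 100,
    horizon: int = 50,
    high_levels: Sequence[int] = (15, 17, 20),
) -> tuple[pd.DataFrame, dict]:
    """Greedy versus value iteration on the compact three-state benchmark,
    averaged over random diagonally dominant transition matrices.

    Returns per-(matrix, policy, level) rows and a summary holding the
    per-level mean costs, the greedy excess over VI at each level, and the
    plateau statistics over ``high_levels``.
    """
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(n_matrices)
    for m, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        t_model = sample_diagonal_dominant_transition(3, rng)
        inst = compact_instance(transitions=t_model, horizon=horizon)
        policies: dict[str, Policy] = {"greedy": GreedyPolicy(inst)}
        for level in levels:
            policies[f"vi_{level}"] = ValueIterationPolicy(inst, level=level)
        results = compare_policies(policies, inst, horizon, reps, rng)
        for name, bd in results.items():
            level = None if name == "greedy" else int(name.split("_")[1])
            rows.append(
                {
                    "matrix": m,
                    "policy": "greedy" if level is None else "value_iteration",
                    "level": level,
                    **bd.to_dict(),
                }
            )
    df = pd.DataFrame(rows)
    greedy_mean = df.loc[df.policy == "greedy", "total_cost"].mean()
    vi_mean = df[df.policy == "value_iteration"].groupby("level")["total_cost"].mean()
    excess_pct = 100.0 * (greedy_mean - vi_mean) / vi_mean  # greedy over VI
    reduction_pct = 100.0 * (greedy_mean - vi_mean) / greedy_mean  # VI below greedy
    high = [l for l in high_levels if l in vi_mean.index]
    summary = {
        "greedy_mean_cost": float(greedy_mean),
        "vi_mean_cost_by_level": {int(k): float(v) for k, v in vi_mean.items()},
        "greedy_excess_pct_by_level": {int(k): float(v) for k, v in excess_pct.items()},
        "vi_reduction_pct_by_level": {int(k): float(v) for k, v in reduction_pct.items()},
        "high_levels": [int(l) for l in high],
        "max_greedy_excess_pct_high": float(excess_pct.loc[high].max()),
        "plateau_vi_reduction_pct": float(reduction_pct.loc[high].mean()),
        "n_rollouts": int(n_matrices * reps),
    }
    return df, summary


def epsilon_experiment(
    seed: int,
    eps_values: Sequence[float] = DEFAULT_GRIDS["epsilon"],
    reps: int = 100,
    horizon: int = 50,
    level: int = 15,
) -> tuple[pd.DataFrame, dict]:
    """Sensor-noise sensitivity: the epsilon emission family on the compact
    benchmark's printed transition matrix, greedy versus VI at one level."""
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(eps_values))
    for eps, child in zip(eps_values, seeds):
        rng = np.random.default_rng(child)
        inst = epsilon_instance(float(eps), horizon=horizon)
        policies = {
            "greedy": GreedyPolicy(inst),
            "value_iteration": ValueIterationPolicy(inst, level=level),
        }
        results = compare_policies(policies, inst, horizon, reps, rng)
        for name, bd in results.items():
            rates = bd.sensor_activation_rates
            rows.append(
                {
                    "epsilon": float(eps),
                    "policy": name,
                    "sensing_fraction": float(np.mean(rates)),
                    **bd.to_dict(),
                }
            )
    df = pd.DataFrame(rows)
    piv = df.pivot_table(index="epsilon", columns="policy", values="total_cost")
    excess = 100.0 * (piv["greedy"] - piv["value_iteration"]) / piv["value_iteration"]
    summary = {
        "greedy_excess_pct_by_epsilon": {float(k): float(v) for k, v in excess.items()},
        "max_excess_pct_below_025": float(excess[excess.index < 0.25].max()),
        "n_rollouts": int(len(eps_values) * reps),
    }
    return df, summary


def stability_experiment(
    seed: int,
    stay_values: Sequence[float] = DEFAULT_GRIDS["stability"],
    reps: int = 100,
    horizon: int = 50,
    level: int = 15,
) -> tuple[pd.DataFrame, dict]:
    """Health-stability sensitivity: symmetric transition family with
    varying self-transition probability, greedy versus VI."""
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(stay_values))
    for stay, child in zip(stay_values, seeds):
        rng = np.random.default_rng(child)
        inst = stability_instance(float(stay), horizon=horizon)
        policies = {
            "greedy": GreedyPolicy(inst),
            "value_iteration": ValueIterationPolicy(inst, level=level),
        }
        results = compare_policies(policies, inst, horizon, reps, rng)
        for name, bd in results.items():
            rows.append({"stay_prob": float(stay), "policy": name, **bd.to_dict()})
    df = pd.DataFrame(rows)
    piv = df.pivot_table(index="stay_prob", columns="policy", values="total_cost")
    ratio = piv["greedy"] / piv["value_iteration"]
    summary = {
        "cost_ratio_by_stay_prob": {float(k): float(v) for k, v in ratio.items()},
        "ratio_at_max_stay": float(ratio.iloc[-1]),
    }
    return df, summary


# ---------------------------------------------------------------------------
# CGM sweeps and cohorts
# ---------------------------------------------------------------------------


def synthetic_cohort(
    seed: int, n_patients: int = 5, n_frames: int = 2000
) -> list[cgm.GlucoseTrace]:
    """Synthetic CGM patients with individually drawn transition matrices."""
    seeds = np.random.SeedSequence(seed).spawn(n_patients)
    traces = []
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        t_model = sample_diagonal_dominant_transition(3, rng)
        traces.append(
            cgm.synth_trace(
                rng,
                transitions=t_model,
                n_frames=n_frames,
                patient_id=f"synthetic-{i + 1:03d}",
            )
        )
    return traces


def cgm_policy_table(
    seed: int,
    n_patients: int = 5,
    n_frames: int = 2000,
    policies: Sequence[str] = ("inclusive", "greedy", "vi"),
    config: Optional[cgm.CgmConfig] = None,
) -> tuple[pd.DataFrame, dict]:
    """Cohort-averaged activation cost (as % of inclusive) and accuracy."""
    config = config or cgm.CgmConfig()
    rows = []
    for trace in synthetic_cohort(seed, n_patients, n_frames):
        for kind in policies:
            report = cgm.fit_and_evaluate(trace, policy=kind, config=config)
            rows.append(report.to_dict())
    df = pd.DataFrame(rows)
    table = df.groupby("policy")[["activation_pct", "accuracy", "fp_rate", "fn_rate"]].mean()
    summary = {
        "activation_pct": {k: float(v) for k, v in table["activation_pct"].items()},
        "accuracy": {k: float(v) for k, v in table["accuracy"].items()},
    }
    return df, summary


def cgm_omega_experiment(
    seed: int,
    omegas: Sequence[float] = DEFAULT_GRIDS["omega"],
    n_frames: int = 2000,
    policy: str = "greedy",
) -> tuple[pd.DataFrame, dict]:
    """Energy/accuracy frontier on one synthetic patient as omega varies."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    trace = cgm.synth_trace(rng, n_frames=n_frames)
    rows = []
    for w in omegas:
        config = dataclasses.replace(cgm.CgmConfig(), omega=float(w))
        report = cgm.fit_and_evaluate(trace, policy=policy, config=config)
        rows.append({"omega": float(w), **report.to_dict()})
    df = pd.DataFrame(rows)
    summary = {
        "activation_by_omega": dict(zip(df["omega"], df["activation_cost"])),
        "misclassification_by_omega": dict(
            zip(df["omega"], df["misclassification_cost"])
        ),
    }
    return df, summary


def _actions_for_k(k: int) -> tuple[tuple[int, ...], ...]:
    if k < 4:
        raise ValidationError("frame-length sweep needs k >= 4 for distinct actions")
    mid = (k // 2,)
    evens = tuple(range(2, k + 1, 2))
    odds = tuple(range(1, k + 1, 2))
    return (mid, evens, odds)


def cgm_frame_length_experiment(
    seed: int,
    k_values: Sequence[int] = DEFAULT_GRIDS["k"],
    n_frames: int = 2000,
) -> tuple[pd.DataFrame, dict]:
    """Greedy/VI cost ratio on one synthetic patient as the frame length
    (slots per decision) varies; actions scale with k (mid slot, even
    slots, odd slots)."""
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(k_values))
    for k, child in zip(k_values, seeds):
        rng = np.random.default_rng(child)
        n = max(200, n_frames * 6 // int(k))  # comparable trace length in slots
        trace = cgm.synth_trace(rng, n_frames=n, k=int(k))
        config = dataclasses.replace(
            cgm.CgmConfig(), k=int(k), actions=_actions_for_k(int(k))
        )
        for kind in ("greedy", "vi"):
            report = cgm.fit_and_evaluate(trace, policy=kind, config=config)
            rows.append({"k": int(k), **report.to_dict()})
    df = pd.DataFrame(rows)
    piv = df.pivot_table(index="k", columns="policy", values="total_cost")
    summary = {
        "cost_ratio_by_k": {
            int(k): float(v) for k, v in (piv["greedy"] / piv["vi"]).items()
        }
    }
    return df, summary


# ---------------------------------------------------------------------------
# named reproduction fixtures and the sweep dispatcher
# ---------------------------------------------------------------------------


def reproduce_fixture(name: str, seed: int = 0, **overrides):
    """Run a named benchmark experiment with its standard parameters.

    ``sec6_1_rollout``: greedy control of the four-state five-sensor
    problem — a 20-epoch state/MAP trace plus per-sensor activation
    percentages (the low-accuracy sensor 5 should essentially never fire).

    ``sec6_2_compact``: the compact-benchmark greedy-versus-VI
    discretization study.

    ``cgm_table1``: the cohort activation/accuracy table on bundled
    synthetic CGM patients.
    """
    if name == "sec6_1_rollout":
        inst = four_state_instance()
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        policy = GreedyPolicy(inst)
        log = rollout(policy, inst, n_epochs=overrides.get("n_epochs", 20), rng=rng)
        bd = evaluate(
            policy,
            inst,
            n_epochs=overrides.get("horizon", 100),
            n_reps=overrides.get("reps", 20),
            rng=rng,
        )
        rates = bd.sensor_activation_rates
        return {
            "trace": log.to_frame(),
            "sensor_activation_pct": [round(100 * float(r), 1) for r in rates],
            "low_accuracy_sensor_rarely_active": bool(rates[4] < 0.05),
            "breakdown": bd.to_dict(),
        }
    if name == "sec6_2_compact":
        df, summary = discretization_experiment(
            seed,
            levels=overrides.get("levels", DEFAULT_GRIDS["discretization"]),
            n_matrices=overrides.get("n_matrices", 30),
            reps=overrides.get("reps", 100),
            horizon=overrides.get("horizon", 50),
        )
        return {"results": df, "summary": summary}
    if name == "cgm_table1":
        df, summary = cgm_policy_table(
            seed,
            n_patients=overrides.get("n_patients", 5),
            n_frames=overrides.get("n_frames", 2000),
        )
        return {"results": df, "summary": summary}
    raise ValidationError(
        f"unknown fixture {name!r}; expected sec6_1_rollout, sec6_2_compact or cgm_table1"
    )


_SWEEPS = {
    "discretization": lambda cfg: discretization_experiment(
        cfg.seed,
        levels=[int(g) for g in cfg.grid],
        n_matrices=cfg.n_matrices,
        reps=cfg.reps,
        horizon=cfg.horizon,
    ),
    "epsilon": lambda cfg: epsilon_experiment(
        cfg.seed, eps_values=cfg.grid, reps=cfg.reps, horizon=cfg.horizon, level=cfg.level
    ),
    "stability": lambda cfg: stability_experiment(
        cfg.seed, stay_values=cfg.grid, reps=cfg.reps, horizon=cfg.horizon, level=cfg.level
    ),
    "omega": lambda cfg: cgm_omega_experiment(
        cfg.seed, omegas=cfg.grid, n_frames=cfg.n_frames
    ),
    "k": lambda cfg: cgm_frame_length_experiment(
        cfg.seed, k_values=[int(g) for g in cfg.grid], n_frames=cfg.n_frames
    ),
}


def run_sweep(
    config: ExperimentConfig, out_dir: Optional[Union[str, Path]] = None
) -> tuple[pd.DataFrame, dict]:
    """Dispatch a sweep by name; optionally write results + resolved config."""
    if config.sweep not in _SWEEPS:
        raise ValidationError(
            f"unknown sweep {config.sweep!r}; expected one of {sorted(_SWEEPS)}"
        )
    df, summary = _SWEEPS[config.sweep](config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{config.sweep}_sweep.csv", index=False)
        (out / f"{config.sweep}_sweep.json").write_text(
            json.dumps({"config": config.to_dict(), "summary": summary}, indent=1)
        )
    return df, summary
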