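"""Serialization: problem instances (YAML/JSON), value tables, traces, results.

Instance documents are plain mappings that round-trip losslessly (floats are
written at full precision).  Value tables are JSON with the discretization
level and an instance fingerprint in the header.  CGM traces use a flat CSV
with columns ``patient_id, timestamp, glucose_mgdl``; real CGM exports must
be converted to this layout before use.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .cgm import GlucoseTrace
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
from .policies import DiscretizedSimplex, ValueTable

__all__ = [
    "instance_to_dict",
    "instance_from_dict",
    "save_instance",
    "load_instance",
    "instance_fingerprint",
    "value_table_to_dict",
    "save_value_table",
    "rollout_to_csv",
    "read_traces",
    "write_traces",
]


def _listify(arr: np.ndarray) -> list:
    return np.asarray(arr, dtype=float).tolist()


def instance_to_dict(instance: ProblemInstance) -> dict:
    doc: dict = {
        "labels": list(instance.states.labels),
        "transition_matrix": _listify(instance.transitions.matrix),
        "emissions": [_listify(a) for a in instance.sensors.emissions],
        "actions": [list(a) for a in instance.actions.actions],
        "horizon": int(instance.horizon),
        "initial_belief": _listify(instance.initial_belief.probs),
        "omega": float(instance.costs.weight),
    }
    if instance.actions.sensor_costs is not None:
        doc["sensor_costs"] = list(instance.actions.sensor_costs)
    else:
        doc["action_costs"] = list(instance.actions.costs)
    if instance.costs.matrix is not None:
        doc["cost_matrix"] = _listify(instance.costs.matrix)
    else:
        doc["false_positive_cost"] = float(instance.costs.false_positive)
        doc["false_negative_cost"] = float(instance.costs.false_negative)
        if instance.costs.swap_roles:
            doc["swap_cost_roles"] = True
    if instance.discount is not None:
        doc["discount"] = float(instance.discount)
    return doc


def instance_from_dict(doc: dict) -> ProblemInstance:
    if "sensor_costs" in doc:
        actions = ActionSet.from_sensor_costs(
            doc["sensor_costs"], actions=doc["actions"]
        )
    else:
        actions = ActionSet(
            actions=tuple(tuple(a) for a in doc["actions"]),
            costs=tuple(doc["action_costs"]),
        )
    costs = CostModel(
        false_positive=doc.get("false_positive_cost"),
        false_negative=doc.get("false_negative_cost"),
        matrix=np.array(doc["cost_matrix"]) if "cost_matrix" in doc else None,
        weight=doc.get("omega", 0.5),
        swap_roles=doc.get("swap_cost_roles", False),
    )
    instance = ProblemInstance(
        states=HealthStateSpace(tuple(doc["labels"])),
        transitions=TransitionModel(np.array(doc["transition_matrix"])),
        sensors=SensorModel(tuple(np.array(a) for a in doc["emissions"])),
        actions=actions,
        costs=costs,
        horizon=int(doc.get("horizon", 50)),
        initial_belief=BeliefState(np.array(doc["initial_belief"]))
        if "initial_belief" in doc
        else None,
        discount=doc.get("discount"),
    )
    return validate_instance(instance)


def save_instance(instance: ProblemInstance, path: Union[str, Path]) -> Path:
    path = Path(path)
    doc = instance_to_dict(instance)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValidationError(f"unknown instance format {path.suffix!r}; use .yaml or .json")
    return path


def load_instance(path: Union[str, Path]) -> ProblemInstance:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return instance_from_dict(doc)


def instance_fingerprint(instance: ProblemInstance) -> str:
    """Short stable digest of the instance document."""
    blob = json.dumps(instance_to_dict(instance), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def value_table_to_dict(
    table: ValueTable, instance: Optional[ProblemInstance] = None
) -> dict:
    header = {
        "discretization_level": table.simplex.level,
        "stationary": table.stationary,
        "horizon": table.horizon,
        "discount": table.discount,
    }
    if instance is not None:
        header["instance_fingerprint"] = instance_fingerprint(instance)
    values = table.values if table.stationary else table.values[0]
    actions = table.actions if table.stationary else table.actions[0]
    entries = {
        str(i): {
            "belief": _listify(table.simplex.points[i]),
            "value": float(values[i]),
            "action": list(table.action_list[int(actions[i])]),
        }
        for i in range(table.simplex.n_points)
    }
    return {"header": header, "entries": entries}


def save_value_table(
    table: ValueTable, path: Union[str, Path], instance: Optional[ProblemInstance] = None
) -> Path:
    path = Path(path)
    path.write_text(json.dumps(value_table_to_dict(table, instance), indent=1))
    return path


def rollout_to_csv(rollout, path: Union[str, Path], seed: Optional[int] = None) -> Path:
    """One CSV row per epoch, with the seed recorded in a comment header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# wbansense rollout; seed={seed}\n")
        rollout.to_frame().to_csv(fh, index=False)
    return path


def read_traces(path: Union[str, Path]) -> list[GlucoseTrace]:
    """Read per-patient traces from the flat trace CSV."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"patient_id", "timestamp", "glucose_mgdl"}
    if not required.issubset(df.columns):
        raise ValidationError(f"trace CSV needs columns {sorted(required)}")
    traces = []
    for pid, sub in df.groupby("patient_id", sort=False):
        sub = sub.sort_values("timestamp")
        traces.append(
            GlucoseTrace(
                patient_id=str(pid),
                timestamps=pd.DatetimeIndex(sub["timestamp"]),
                glucose=sub["glucose_mgdl"].to_numpy(),
            )
        )
    return traces


def write_traces(traces, path: Union[str, Path]) -> Path:
    path = Path(path)
    pd.concat([t.to_frame() for t in traces], ignore_index=True).to_csv(
        path, index=False
    )
    return path
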