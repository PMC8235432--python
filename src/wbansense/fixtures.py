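"""Ready-made problem instances used throughout the examples and tests.

These are the standard small benchmark configurations for the sensing
controller: a three-state cyclic chain with perfect one-state detectors
(``motivating_instance``), a four-state / five-sensor monitoring problem
with heterogeneous sensor accuracies and a full misclassification cost
matrix (``four_state_instance``), and a compact three-state / two-sensor
problem used for greedy-versus-optimal comparisons and the sensitivity
sweeps (``compact_instance`` and its epsilon / stability variants).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .model import (
    ActionSet,
    BeliefState,
    CostModel,
    HealthStateSpace,
    ProblemInstance,
    SensorModel,
    TransitionModel,
    make_epsilon_sensors,
    make_stability_transition,
    validate_instance,
)

__all__ = [
    "motivating_instance",
    "four_state_instance",
    "compact_instance",
    "epsilon_instance",
    "stability_instance",
    "COMPACT_T",
    "COMPACT_DETECTION",
]

#: compact three-state benchmark transition matrix
COMPACT_T = np.array(
    [
        [0.90, 0.06, 0.04],
        [0.04, 0.90, 0.06],
        [0.01, 0.04, 0.95],
    ]
)

#: compact benchmark binary detection matrix, Pr(output "1" | state)
COMPACT_DETECTION = np.array(
    [
        [0.90, 0.10, 0.50],
        [0.50, 0.90, 0.10],
    ]
)

#: compact benchmark explicit misclassification cost matrix
COMPACT_CM = np.array(
    [
        [0.0, 33.0, 42.0],
        [80.0, 0.0, 25.0],
        [17.0, 8.0, 0.0],
    ]
)


def motivating_instance(
    taus: Sequence[float] = (0.1, 0.1, 0.1),
    sensor_cost: float = 1.0,
    cfp: float = 100.0,
    cfn: float = 100.0,
    omega: float = 0.5,
    horizon: int = 20,
    initial_belief: Optional[BeliefState] = None,
) -> ProblemInstance:
    """Three-state cycle with three perfect one-state detectors.

    State h1 (least healthy) returns to the healthiest state h3 with
    probability ``taus[0]``; h2 and h3 each decay to their less-healthy
    neighbour with probabilities ``taus[1]`` and ``taus[2]``.  Sensor ``n``
    outputs "1" exactly when the patient is in state ``h_n``.  With
    accurate sensing and cheap sensors, the efficient closed-loop policy
    activates a single sensor per epoch once the state is known.
    """
    t1, t2, t3 = taus
    t_mat = np.array(
        [
            [1 - t1, 0.0, t1],
            [t2, 1 - t2, 0.0],
            [0.0, t3, 1 - t3],
        ]
    )
    det = np.eye(3)
    inst = ProblemInstance(
        states=HealthStateSpace.of_size(3),
        transitions=TransitionModel(t_mat),
        sensors=SensorModel.from_detection_probs(det),
        actions=ActionSet.from_sensor_costs([sensor_cost] * 3),
        costs=CostModel(false_positive=cfp, false_negative=cfn, weight=omega),
        horizon=horizon,
        initial_belief=initial_belief,
    )
    return validate_instance(inst)


def four_state_instance(
    omega: float = 0.5, horizon: int = 50
) -> ProblemInstance:
    """Four states, five binary sensors of very different quality and cost.

    Sensor 1 is an expensive, highly accurate detector of the critical
    state h1; sensors 2-4 are cheap detectors of individual states; sensor
    5 is cheap but nearly uninformative.  Misclassification costs are given
    as a full matrix that penalizes missing the severe states hardest.
    """
    t_mat = np.array(
        [
            [0.90, 0.04, 0.04, 0.02],
            [0.02, 0.90, 0.04, 0.04],
            [0.01, 0.01, 0.90, 0.08],
            [0.01, 0.01, 0.03, 0.95],
        ]
    )
    det = np.array(
        [
            [0.99, 0.01, 0.50, 0.50],
            [0.50, 0.90, 0.10, 0.50],
            [0.50, 0.50, 0.90, 0.10],
            [0.90, 0.10, 0.50, 0.50],
            [0.60, 0.40, 0.60, 0.50],
        ]
    )
    cs = [5.0, 1.0, 1.0, 1.0, 0.2]
    cm = np.array(
        [
            [0.0, 100.0, 125.0, 150.0],
            [250.0, 0.0, 75.0, 100.0],
            [50.0, 250.0, 0.0, 50.0],
            [75.0, 60.0, 450.0, 0.0],
        ]
    )
    inst = ProblemInstance(
        states=HealthStateSpace.of_size(4),
        transitions=TransitionModel(t_mat),
        sensors=SensorModel.from_detection_probs(det),
        actions=ActionSet.from_sensor_costs(cs),
        costs=CostModel(matrix=cm, weight=omega),
        horizon=horizon,
    )
    return validate_instance(inst)


def compact_instance(
    transitions: Optional[TransitionModel] = None,
    sensors: Optional[SensorModel] = None,
    cfp: float = 50.0,
    cfn: float = 100.0,
    omega: float = 0.5,
    horizon: int = 50,
    cost_matrix: Optional[np.ndarray] = None,
) -> ProblemInstance:
    """Compact three-state / two-sensor benchmark.

    Sensor 1 separates h1 from h2, sensor 2 separates h2 from h3; both cost
    2 energy units.  By default misclassification uses the constant
    CFP/CFN structure; pass ``cost_matrix=COMPACT_CM`` for the explicit
    matrix variant.
    """
    if transitions is None:
        transitions = TransitionModel(COMPACT_T)
    if sensors is None:
        sensors = SensorModel.from_detection_probs(COMPACT_DETECTION)
    if cost_matrix is not None:
        costs = CostModel(matrix=cost_matrix, weight=omega)
    else:
        costs = CostModel(false_positive=cfp, false_negative=cfn, weight=omega)
    inst = ProblemInstance(
        states=HealthStateSpace.of_size(3),
        transitions=transitions,
        sensors=sensors,
        actions=ActionSet.from_sensor_costs([2.0, 2.0]),
        costs=costs,
        horizon=horizon,
    )
    return validate_instance(inst)


def epsilon_instance(epsilon: float, omega: float = 0.5, horizon: int = 50) -> ProblemInstance:
    """Compact benchmark with the epsilon-noise sensor family."""
    return compact_instance(
        sensors=make_epsilon_sensors(epsilon), omega=omega, horizon=horizon
    )


def stability_instance(
    stay_prob: float, omega: float = 0.5, horizon: int = 50
) -> ProblemInstance:
    """Compact benchmark with the symmetric stability transition family."""
    return compact_instance(
        transitions=make_stability_transition(stay_prob, 3),
        omega=omega,
        horizon=horizon,
    )
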