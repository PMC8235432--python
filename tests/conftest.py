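import numpy as np
import pytest

from wbansense.model import (
    ActionSet,
    BeliefState,
    CostModel,
    HealthStateSpace,
    ProblemInstance,
    SensorModel,
    TransitionModel,
    validate_instance,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_state_instance():
    """J=2, one noisy binary sensor: small enough for hand enumeration."""
    return validate_instance(
        ProblemInstance(
            states=HealthStateSpace.of_size(2),
            transitions=TransitionModel([[0.9, 0.1], [0.2, 0.8]]),
            sensors=SensorModel.from_detection_probs([[0.2, 0.7]]),
            actions=ActionSet.from_sensor_costs([3.0]),
            costs=CostModel(false_positive=50.0, false_negative=100.0, weight=0.5),
            horizon=5,
        )
    )


@pytest.fixture
def accurate_two_state_instance():
    """Lemma-2 setting: accurate invertible binary sensors, all-on/all-off.

    The initial belief (0.6, 0.4) is the chain's stationary vector, so its
    idle-propagated images stay put; pure states propagate onto the d=20
    grid for the first few steps, keeping the whole reachable set on-grid.
    """
    return validate_instance(
        ProblemInstance(
            states=HealthStateSpace.of_size(2),
            transitions=TransitionModel([[0.8, 0.2], [0.3, 0.7]]),
            sensors=SensorModel.from_detection_probs([[1.0, 0.0], [0.0, 1.0]]),
            actions=ActionSet.from_sensor_costs([1.0, 1.0], actions=[(0, 0), (1, 1)]),
            costs=CostModel(false_positive=100.0, false_negative=100.0, weight=0.5),
            horizon=3,
            initial_belief=BeliefState(np.array([0.6, 0.4])),
        )
    )
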