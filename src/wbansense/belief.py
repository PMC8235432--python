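"""Recursive Bayes filtering over the hidden health state.

The controller never observes the health state directly; it tracks a belief
state, the posterior distribution over states given all past sensor
outputs.  Because the health state is Markov and sensor outputs are
conditionally independent given the state, the belief is a sufficient
statistic and can be updated recursively:

    predict   p_j   = sum_i T[i, j] * b_i
    condition b'_j  = p_j * f(l, j) / sum_k p_k * f(l, k)

where ``f(l, j)`` is the product over active sensors of their emission
probabilities for the observed symbols (inactive sensors contribute the
neutral factor 1).

This module also evaluates the expected misclassification cost of a belief:
for each candidate classification ``h_j`` the per-state cost ``rho_j``
charges the false-positive unit cost for belief mass on less-healthy states
and the false-negative unit cost for mass on healthier states; the total
``rho`` averages ``rho_j`` under the belief itself.
"""

from __future__ import annotations

from itertools import product
from typing import Optional, Sequence

import numpy as np

from .model import (
    ATOL,
    BeliefState,
    CostModel,
    ProblemInstance,
    SensorModel,
    TransitionModel,
    ValidationError,
)

__all__ = [
    "INACTIVE",
    "Observation",
    "ImpossibleEvidenceError",
    "predict",
    "emission_product",
    "observation_space",
    "observation_likelihood",
    "belief_update",
    "posterior_from_weights",
    "misclassification_cost",
    "map_state",
]

#: marker for a deactivated sensor's (absent) output
INACTIVE = None

#: an observation is one entry per sensor: a symbol in 0..Lambda-1, or INACTIVE
Observation = tuple

class ImpossibleEvidenceError(ValueError):
    """The observation has probability zero under the current belief.

    This cannot happen when observations are sampled from the model itself;
    on external data it flags a model misfit and is never silently
    renormalized away.
    """


def _belief_array(b) -> np.ndarray:
    return np.asarray(b.probs if isinstance(b, BeliefState) else b, dtype=float)


def predict(b: BeliefState, transitions: TransitionModel) -> BeliefState:
    """One-step belief propagation through the Markov chain (no observation)."""
    vec = _belief_array(b)
    m = transitions.matrix
    if vec.shape[0] != m.shape[0]:
        raise ValidationError(
            f"predict: belief has {vec.shape[0]} states, transition matrix {m.shape[0]}"
        )
    return BeliefState(vec @ m)


def emission_product(observation: Observation, sensors: SensorModel) -> np.ndarray:
    """The length-J likelihood vector ``f(l, .)``.

    Component ``j`` is the product over sensors of Pr(observed symbol |
    state ``h_{j+1}``); a deactivated sensor contributes the factor 1.
    """
    if len(observation) != sensors.n_sensors:
        raise ValidationError(
            f"observation has {len(observation)} entries for {sensors.n_sensors} sensors"
        )
    weights = np.ones(sensors.n_states)
    for n, symbol in enumerate(observation):
        if symbol is INACTIVE:
            continue
        symbol = int(symbol)
        if not 0 <= symbol < sensors.alphabet_size:
            raise ValidationError(
                f"sensor {n + 1} symbol {symbol} outside alphabet 0..{sensors.alphabet_size - 1}"
            )
        weights = weights * sensors.emissions[n][symbol]
    return weights


def observation_space(action: Sequence[int], sensors: SensorModel) -> list[Observation]:
    """Enumerate L(s): all output vectors possible under activation ``action``."""
    choices = [
        range(sensors.alphabet_size) if active else (INACTIVE,) for active in action
    ]
    return [tuple(c) for c in product(*choices)]


def observation_likelihood(
    b: BeliefState, action: Sequence[int], instance: ProblemInstance
) -> dict[Observation, float]:
    """Predictive distribution of the next observation under ``action``.

    Support is exactly L(s); probabilities sum to one.
    """
    instance.actions.index(action)  # raises if the action is not allowed
    p = predict(b, instance.transitions).probs
    out: dict[Observation, float] = {}
    for obs in observation_space(action, instance.sensors):
        out[obs] = float(emission_product(obs, instance.sensors) @ p)
    return out


def posterior_from_weights(predicted: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Condition a predicted belief on a likelihood-weight vector."""
    unnorm = np.asarray(predicted, dtype=float) * np.asarray(weights, dtype=float)
    norm = unnorm.sum()
    if norm <= 0.0:
        raise ImpossibleEvidenceError(
            "observation has probability 0 under the current belief"
        )
    return unnorm / norm


def belief_update(
    b: BeliefState, observation: Observation, instance: ProblemInstance
) -> BeliefState:
    """Recursive Bayes update: predict through T, then condition on ``l``.

    With an all-inactive observation this reduces to the bare prediction
    ``T' b``.  A zero-probability observation raises
    :class:`ImpossibleEvidenceError`.
    """
    p = predict(b, instance.transitions).probs
    w = emission_product(observation, instance.sensors)
    return BeliefState(posterior_from_weights(p, w))


def misclassification_cost(
    b_next: BeliefState, costs: CostModel
) -> tuple[np.ndarray, float]:
    """Per-state costs ``rho_j`` and the belief-averaged total ``rho``.

    ``rho_j = CFP * sum_{i<j} b_i + CFN * sum_{i>j} b_i`` in scalar mode, or
    ``rho_j = sum_i Cm[i, j] * b_i`` with an explicit cost matrix;
    ``rho = sum_j b_j * rho_j``.
    """
    vec = _belief_array(b_next)
    cm = costs.cost_matrix(vec.shape[0])
    rho_j = vec @ cm
    return rho_j, float(vec @ rho_j)


def map_state(b: BeliefState) -> int:
    """Most likely health state (1-based); ties go to the lower index.

    Breaking ties toward the less healthy state is the conservative
    clinical choice.
    """
    return int(np.argmax(_belief_array(b))) + 1
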