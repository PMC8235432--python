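from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wbansense.belief import (
    INACTIVE,
    ImpossibleEvidenceError,
    belief_update,
    emission_product,
    map_state,
    misclassification_cost,
    observation_likelihood,
    observation_space,
    predict,
)
from wbansense.fixtures import motivating_instance
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

# ---------------------------------------------------------------------------
# oracle: brute-force Bayes by enumerating all hidden-state paths
# ---------------------------------------------------------------------------


def brute_force_belief(instance, observations):
    """Posterior over h_t from explicit path enumeration.

    Sums b0[h0] * prod T[h_k, h_{k+1}] * prod f(l_k, h_k) over all hidden
    paths, then normalizes the marginal of the final state.  Independent of
    the recursive filter.
    """
    n = instance.n_states
    t_mat = instance.transitions.matrix
    b0 = instance.initial_belief.probs
    horizon = len(observations)
    weights = [emission_product(o, instance.sensors) for o in observations]
    marginal = np.zeros(n)
    for path in product(range(n), repeat=horizon + 1):
        w = b0[path[0]]
        for k in range(horizon):
            w *= t_mat[path[k], path[k + 1]] * weights[k][path[k + 1]]
        marginal[path[-1]] += w
    return marginal / marginal.sum()


def random_small_instance(seed):
    rng = np.random.default_rng(seed)
    n_states = int(rng.integers(2, 5))
    n_sensors = int(rng.integers(1, 4))
    alphabet = int(rng.integers(2, 4))
    t_mat = rng.dirichlet(np.ones(n_states), size=n_states)
    emissions = tuple(
        rng.dirichlet(np.ones(alphabet), size=n_states).T for _ in range(n_sensors)
    )
    b0 = rng.dirichlet(np.ones(n_states))
    return validate_instance(
        ProblemInstance(
            states=HealthStateSpace.of_size(n_states),
            transitions=TransitionModel(t_mat),
            sensors=SensorModel(emissions),
            actions=ActionSet.from_sensor_costs(rng.uniform(0.5, 2, n_sensors)),
            costs=CostModel(false_positive=50.0, false_negative=100.0),
            initial_belief=BeliefState(b0),
            horizon=5,
        )
    )


# ---------------------------------------------------------------------------
# prediction and emission products
# ---------------------------------------------------------------------------


class TestPredict:
    def test_identity_transition_fixed_point(self):
        b = BeliefState(np.array([0.3, 0.2, 0.5]))
        assert np.allclose(predict(b, TransitionModel(np.eye(3))).probs, b.probs)

    def test_two_state_hand_value(self):
        # oracle: marginalize the joint (h_t, h_{t+1}) mass by hand
        b = BeliefState(np.array([0.5, 0.5]))
        t = TransitionModel([[0.9, 0.1], [0.2, 0.8]])
        assert np.allclose(predict(b, t).probs, [0.55, 0.45])

    def test_no_sensing_update_equals_prediction(self, two_state_instance):
        b = BeliefState(np.array([0.35, 0.65]))
        via_update = belief_update(b, (INACTIVE,), two_state_instance)
        via_predict = predict(b, two_state_instance.transitions)
        assert np.allclose(via_update.probs, via_predict.probs)


class TestEmissionProduct:
    def test_all_inactive_is_neutral(self):
        inst = motivating_instance()
        assert np.array_equal(
            emission_product((INACTIVE,) * 3, inst.sensors), np.ones(3)
        )

    def test_perfect_sensor_gives_indicator(self):
        inst = motivating_instance()
        w = emission_product((1, INACTIVE, INACTIVE), inst.sensors)
        assert np.array_equal(w, [1.0, 0.0, 0.0])

    def test_two_sensor_product_matches_manual_lookup(self):
        det = np.array([[0.9, 0.1, 0.5], [0.5, 0.9, 0.1]])
        sensors = SensorModel.from_detection_probs(det)
        w = emission_product((1, 0), sensors)
        assert np.allclose(w, det[0] * (1 - det[1]))

    def test_symbol_outside_alphabet_rejected(self):
        sensors = SensorModel.from_detection_probs([[0.9, 0.1]])
        with pytest.raises(Exception, match="alphabet"):
            emission_product((2,), sensors)


class TestObservationLikelihood:
    def test_idle_action_single_certain_observation(self, two_state_instance):
        like = observation_likelihood(
            two_state_instance.initial_belief, (0,), two_state_instance
        )
        assert like == {(INACTIVE,): pytest.approx(1.0)}

    def test_two_state_hand_value(self):
        # oracle: enumerate the joint (h_{t+1}, l) under T = identity
        inst = validate_instance(
            ProblemInstance(
                states=HealthStateSpace.of_size(2),
                transitions=TransitionModel(np.eye(2)),
                sensors=SensorModel.from_detection_probs([[0.9, 0.2]]),
                actions=ActionSet.from_sensor_costs([1.0]),
                costs=CostModel(false_positive=1.0, false_negative=1.0),
            )
        )
        like = observation_likelihood(BeliefState(np.array([0.6, 0.4])), (1,), inst)
        assert like[(1,)] == pytest.approx(0.62)
        assert like[(0,)] == pytest.approx(0.38)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_support_is_observation_space_and_normalized(self, seed):
        inst = random_small_instance(seed)
        action = inst.actions.actions[
            int(np.random.default_rng(seed + 1).integers(inst.actions.n_actions))
        ]
        like = observation_likelihood(inst.initial_belief, action, inst)
        assert set(like) == set(observation_space(action, inst.sensors))
        assert sum(like.values()) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# recursive update
# ---------------------------------------------------------------------------


class TestBeliefUpdate:
    def test_two_state_hand_posterior(self):
        inst = validate_instance(
            ProblemInstance(
                states=HealthStateSpace.of_size(2),
                transitions=TransitionModel([[0.9, 0.1], [0.2, 0.8]]),
                sensors=SensorModel.from_detection_probs([[0.2, 0.7]]),
                actions=ActionSet.from_sensor_costs([1.0]),
                costs=CostModel(false_positive=1.0, false_negative=1.0),
            )
        )
        # oracle: condition the enumerated joint (h_t, h_{t+1}, l) on l = 1:
        # prediction (0.55, 0.45), weights (0.2, 0.7) -> (0.11, 0.315)/0.425
        post = belief_update(BeliefState(np.array([0.5, 0.5])), (1,), inst)
        assert np.allclose(post.probs, [0.11 / 0.425, 0.315 / 0.425])

    def test_accurate_sensors_collapse_to_indicator(self):
        inst = motivating_instance()
        post = belief_update(BeliefState.uniform(3), (0, 1, 0), inst)
        assert np.allclose(post.probs, [0.0, 1.0, 0.0])

    def test_impossible_evidence_raises(self):
        inst = motivating_instance(initial_belief=BeliefState.pure(2, 3))
        # from pure h2 the chain can only reach h1 or h2, never h3
        with pytest.raises(ImpossibleEvidenceError):
            belief_update(inst.initial_belief, (0, 0, 1), inst)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_filter_matches_brute_force_enumeration(self, seed):
        """The recursive filter is a sufficient statistic: after any
        model-consistent observation sequence it equals the posterior from
        full hidden-path enumeration (sup-norm 1e-9)."""
        inst = random_small_instance(seed)
        rng = np.random.default_rng(seed + 99)
        horizon = int(rng.integers(1, 6))
        belief = inst.initial_belief
        observations = []
        state = int(rng.choice(inst.n_states, p=inst.initial_belief.probs))
        for _ in range(horizon):
            state = int(rng.choice(inst.n_states, p=inst.transitions.matrix[state]))
            action = inst.actions.actions[int(rng.integers(inst.actions.n_actions))]
            obs = tuple(
                int(rng.choice(inst.sensors.alphabet_size, p=inst.sensors.emissions[n][:, state]))
                if active
                else INACTIVE
                for n, active in enumerate(action)
            )
            observations.append(obs)
            belief = belief_update(belief, obs, inst)
            assert belief.probs.sum() == pytest.approx(1.0, abs=1e-9)
        expected = brute_force_belief(inst, observations)
        assert np.max(np.abs(belief.probs - expected)) < 1e-9

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_law_of_total_probability(self, seed):
        """Mixing posteriors by observation probability recovers the
        prediction, for every action."""
        inst = random_small_instance(seed)
        b = inst.initial_belief
        p = predict(b, inst.transitions).probs
        for action in inst.actions.actions:
            like = observation_likelihood(b, action, inst)
            mix = np.zeros(inst.n_states)
            for obs, prob in like.items():
                if prob > 0:
                    mix += prob * belief_update(b, obs, inst).probs
            assert np.max(np.abs(mix - p)) < 1e-9


# ---------------------------------------------------------------------------
# misclassification costs and MAP state
# ---------------------------------------------------------------------------


class TestMisclassificationCost:
    def test_degenerate_belief_costs_nothing(self):
        costs = CostModel(false_positive=50.0, false_negative=100.0)
        _, rho = misclassification_cost(BeliefState.pure(2, 4), costs)
        assert rho == 0.0

    def test_symmetric_two_state(self):
        costs = CostModel(false_positive=7.0, false_negative=7.0)
        _, rho = misclassification_cost(BeliefState(np.array([0.5, 0.5])), costs)
        assert rho == pytest.approx(3.5)

    def test_hand_example_scalar_mode(self):
        # oracle: hand evaluation of the per-state cost definition
        costs = CostModel(false_positive=50.0, false_negative=100.0)
        rho_j, rho = misclassification_cost(BeliefState(np.array([0.5, 0.5])), costs)
        assert np.allclose(rho_j, [50.0, 25.0])
        assert rho == pytest.approx(37.5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matrix_mode_reproduces_scalar_mode(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        b = BeliefState(rng.dirichlet(np.ones(n)))
        cfp, cfn = rng.uniform(0, 100, 2)
        scalar = CostModel(false_positive=cfp, false_negative=cfn)
        i, j = np.indices((n, n))
        matrix = CostModel(matrix=np.where(i < j, cfp, np.where(i > j, cfn, 0.0)))
        rj_s, r_s = misclassification_cost(b, scalar)
        rj_m, r_m = misclassification_cost(b, matrix)
        assert np.allclose(rj_s, rj_m)
        assert r_s == pytest.approx(r_m)


class TestMapState:
    @pytest.mark.parametrize(
        "belief, expected",
        [
            ([0.1, 0.2, 0.7], 3),
            ([0.5, 0.5], 1),  # tie goes to the less healthy state
            ([0.0, 1.0, 0.0], 2),
        ],
    )
    def test_map_state(self, belief, expected):
        assert map_state(BeliefState(np.array(belief))) == expected
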