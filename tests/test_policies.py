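import dataclasses
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wbansense.belief import emission_product, observation_space
from wbansense.fixtures import compact_instance, epsilon_instance, motivating_instance
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
from wbansense.policies import (
    GreedyPolicy,
    ValueIterationPolicy,
    enumerate_grid,
    exact_dp_accurate,
    greedy_action,
    inclusive_action,
    reachable_beliefs,
    snap_to_grid,
    value_iteration_discounted,
    value_iteration_finite,
)

# ---------------------------------------------------------------------------
# simplex enumeration and snapping
# ---------------------------------------------------------------------------


class TestGrid:
    def test_two_state_level_two_exhaustive(self):
        pts = enumerate_grid(2, 2).points
        assert {tuple(p) for p in pts} == {(0.0, 1.0), (0.5, 0.5), (1.0, 0.0)}

    @pytest.mark.parametrize("n_states, level", [(3, 15), (4, 5), (2, 20), (3, 9)])
    def test_point_count_is_stars_and_bars(self, n_states, level):
        grid = enumerate_grid(n_states, level)
        assert grid.n_points == comb(level + n_states - 1, n_states - 1)
        assert np.allclose(grid.points.sum(axis=1), 1.0)

    def test_snap_worked_example(self):
        # level 0.2 on 4 states: the canonical snap of an off-grid belief
        grid = enumerate_grid(4, 5)
        snapped = snap_to_grid(BeliefState(np.array([0.17, 0.35, 0.40, 0.08])), grid)
        assert np.allclose(snapped, [0.20, 0.40, 0.40, 0.00])

    def test_snap_is_identity_on_grid_points(self):
        grid = enumerate_grid(3, 7)
        for p in grid.points:
            assert np.array_equal(snap_to_grid(BeliefState(p), grid), p)

    def test_snap_two_state_distance_scan(self):
        # oracle: exhaustive distances to {(0,1), (.5,.5), (1,0)}
        grid = enumerate_grid(2, 2)
        snapped = snap_to_grid(BeliefState(np.array([0.3, 0.7])), grid)
        assert np.allclose(snapped, [0.5, 0.5])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_snap_quasi_isometry(self, seed):
        """Snapping moves a belief by at most the grid resolution bound,
        so distances to any other belief grow by at most 2*J/d."""
        rng = np.random.default_rng(seed)
        n, d = int(rng.integers(2, 5)), int(rng.integers(2, 12))
        grid = enumerate_grid(n, d)
        b = rng.dirichlet(np.ones(n))
        c = rng.dirichlet(np.ones(n))
        s = snap_to_grid(BeliefState(b), grid)
        assert np.abs(s - b).sum() <= 2 * n / d + 1e-12
        assert np.abs(s - c).sum() <= np.abs(b - c).sum() + 2 * n / d + 1e-12


# ---------------------------------------------------------------------------
# greedy and inclusive
# ---------------------------------------------------------------------------


def _perfect_sensor_instance(cost):
    return validate_instance(
        ProblemInstance(
            states=HealthStateSpace.of_size(2),
            transitions=TransitionModel(np.eye(2)),
            sensors=SensorModel.from_detection_probs([[1.0, 0.0]]),
            actions=ActionSet.from_sensor_costs([cost]),
            costs=CostModel(false_positive=100.0, false_negative=100.0, weight=0.5),
        )
    )


class TestGreedy:
    def test_pure_energy_minimization_idles(self):
        inst = compact_instance(omega=0.0)
        assert greedy_action(BeliefState.uniform(3), inst) == (0, 0)

    def test_perfect_sensor_activation_threshold(self):
        # hand enumeration: activate iff 0.5*c < omega*rho(prediction) = 25
        b = BeliefState(np.array([0.5, 0.5]))
        assert greedy_action(b, _perfect_sensor_instance(10.0)) == (1,)
        assert greedy_action(b, _perfect_sensor_instance(100.0)) == (0,)

    def test_zero_information_sensors_pick_cheapest_action(self):
        inst = epsilon_instance(0.5)
        assert greedy_action(BeliefState.uniform(3), inst) == (0, 0)

    def test_returned_action_always_in_action_set(self, rng):
        inst = compact_instance()
        for _ in range(20):
            b = BeliefState(rng.dirichlet(np.ones(3)))
            assert greedy_action(b, inst) in inst.actions.actions


class TestInclusive:
    def test_all_sensors_on(self):
        inst = compact_instance()
        assert inclusive_action(inst) == (1, 1)

    def test_missing_all_on_action_rejected(self):
        inst = compact_instance()
        trimmed = ActionSet(
            actions=tuple(a for a in inst.actions.actions if a != (1, 1)),
            costs=tuple(
                c for a, c in zip(inst.actions.actions, inst.actions.costs) if a != (1, 1)
            ),
        )
        broken = ProblemInstance(
            states=inst.states,
            transitions=inst.transitions,
            sensors=inst.sensors,
            actions=trimmed,
            costs=inst.costs,
        )
        with pytest.raises(Exception, match="all-active"):
            inclusive_action(broken)


# ---------------------------------------------------------------------------
# value iteration
# ---------------------------------------------------------------------------


def _bellman_oracle(instance, simplex, belief, t):
    """Recursive enumeration of all action/observation trees with snapped
    successors: an independent evaluation of the dynamic program."""
    if t >= instance.horizon:
        return 0.0
    t_mat = instance.transitions.matrix
    cm = instance.cost_matrix()
    omega = instance.omega
    best = np.inf
    for idx, action in enumerate(instance.actions.actions):
        p = belief @ t_mat
        total = (1.0 - omega) * instance.actions.costs[idx]
        for obs in observation_space(action, instance.sensors):
            w = emission_product(obs, instance.sensors)
            pr = float(p @ w)
            if pr <= 0:
                continue
            q = p * w / pr
            rho = float(q @ (q @ cm))
            total += pr * (
                omega * rho + _bellman_oracle(instance, simplex, snap_to_grid(q, simplex), t + 1)
            )
        best = min(best, total)
    return best


class TestValueIterationFinite:
    def test_zero_horizon_terminal_values(self):
        inst = dataclasses.replace(compact_instance(), horizon=0)
        table = value_iteration_finite(inst, enumerate_grid(3, 5))
        assert np.all(table.values == 0.0)

    def test_matches_tree_enumeration_oracle(self, two_state_instance):
        inst = dataclasses.replace(two_state_instance, horizon=2)
        simplex = enumerate_grid(2, 10)
        table = value_iteration_finite(inst, simplex)
        for i in range(simplex.n_points):
            expected = _bellman_oracle(inst, simplex, simplex.points[i], 0)
            assert table.values[0][i] == pytest.approx(expected, abs=1e-9)

    def test_actions_respect_action_set(self):
        inst = compact_instance(horizon=10)
        table = value_iteration_finite(inst, enumerate_grid(3, 9))
        used = {table.action_list[i] for i in np.unique(table.actions)}
        assert used <= set(inst.actions.actions)

    def test_value_table_round_trip(self, tmp_path):
        from wbansense.io import save_value_table
        import json

        inst = compact_instance(horizon=5)
        table = value_iteration_finite(inst, enumerate_grid(3, 5))
        path = save_value_table(table, tmp_path / "table.json", inst)
        doc = json.loads(path.read_text())
        assert doc["header"]["discretization_level"] == 5
        assert "instance_fingerprint" in doc["header"]
        entry = doc["entries"]["0"]
        assert entry["value"] == pytest.approx(table.values[0][0])


class TestValueIterationDiscounted:
    def test_zero_cost_instance_has_zero_fixed_point(self):
        inst = validate_instance(
            ProblemInstance(
                states=HealthStateSpace.of_size(2),
                transitions=TransitionModel([[0.9, 0.1], [0.2, 0.8]]),
                sensors=SensorModel.from_detection_probs([[0.8, 0.1]]),
                actions=ActionSet.from_sensor_costs([0.0]),
                costs=CostModel(false_positive=0.0, false_negative=0.0),
                discount=0.9,
            )
        )
        table = value_iteration_discounted(inst, enumerate_grid(2, 5))
        assert np.allclose(table.values, 0.0)

    def test_missing_discount_rejected(self, two_state_instance):
        with pytest.raises(Exception, match="discount"):
            value_iteration_discounted(two_state_instance, enumerate_grid(2, 5))

    def test_matches_long_horizon_bellman_iteration(self, two_state_instance):
        """Stationary solution equals 200 applications of the discounted
        Bellman operator (written out in the test) within 10x the stopping
        tolerance."""
        inst = dataclasses.replace(two_state_instance, discount=0.95)
        simplex = enumerate_grid(2, 5)
        tol = 1e-8
        table = value_iteration_discounted(inst, simplex, tol=tol)

        t_mat = inst.transitions.matrix
        cm = inst.cost_matrix()
        omega, gamma = inst.omega, inst.discount
        values = np.zeros(simplex.n_points)
        deltas = []
        for _ in range(200):
            new = np.empty_like(values)
            for i, b in enumerate(simplex.points):
                best = np.inf
                for idx, action in enumerate(inst.actions.actions):
                    p = b @ t_mat
                    total = (1 - omega) * inst.actions.costs[idx]
                    for obs in observation_space(action, inst.sensors):
                        w = emission_product(obs, inst.sensors)
                        pr = float(p @ w)
                        if pr <= 0:
                            continue
                        q = p * w / pr
                        rho = float(q @ (q @ cm))
                        j = int(simplex.snap_index(q[None, :])[0])
                        total += pr * (omega * rho + gamma * values[j])
                    best = min(best, total)
                new[i] = best
            deltas.append(np.max(np.abs(new - values)))
            values = new
        # contraction: successive Bellman sweeps shrink by at least gamma
        for a, b in zip(deltas[1:6], deltas[:5]):
            assert a <= gamma * b + 1e-9
        # after 200 sweeps from zero the residual is at most gamma^200 * ||V*||
        bound = gamma**200 * np.max(table.values) + 10 * tol
        assert np.max(np.abs(values - table.values)) <= bound


# ---------------------------------------------------------------------------
# accurate-sensor special case
# ---------------------------------------------------------------------------


def _accurate_instance(n_states, horizon, sensor_cost=1.0, seed=3):
    rng = np.random.default_rng(seed)
    t_mat = rng.dirichlet(np.ones(n_states) * 5, size=n_states)
    return validate_instance(
        ProblemInstance(
            states=HealthStateSpace.of_size(n_states),
            transitions=TransitionModel(t_mat),
            sensors=SensorModel.from_detection_probs(np.eye(n_states)),
            actions=ActionSet.from_sensor_costs(
                [sensor_cost] * n_states, actions=[(0,) * n_states, (1,) * n_states]
            ),
            costs=CostModel(false_positive=50.0, false_negative=100.0, weight=0.5),
            horizon=horizon,
        )
    )


def _eq19_forward_expansion(instance, b0, horizon):
    """Breadth-first oracle: every belief either propagates through T or
    collapses to a pure state.  Carries full precision, dedups on rounding."""
    t_mat = instance.transitions.matrix
    n = instance.n_states
    frontier = {tuple(np.asarray(b0.probs))}
    reached = {}
    for _ in range(horizon):
        nxt = set()
        for b in frontier:
            nxt.add(tuple(np.array(b) @ t_mat))
            for j in range(n):
                nxt.add(tuple(np.eye(n)[j]))
        for b in nxt:
            reached.setdefault(tuple(np.round(b, 12)), b)
        frontier = nxt
    return set(reached)


class TestReachableBeliefs:
    def test_bound_holds(self):
        inst = _accurate_instance(4, 10)
        assert len(reachable_beliefs(inst)) <= 10 * 5

    def test_one_step_set(self):
        inst = _accurate_instance(3, 1)
        reached = {tuple(np.round(b, 12)) for b in reachable_beliefs(inst)}
        expected = {
            tuple(np.round(inst.initial_belief.probs @ inst.transitions.matrix, 12))
        } | {tuple(np.eye(3)[j]) for j in range(3)}
        assert reached == expected

    def test_matches_forward_expansion_oracle(self):
        inst = _accurate_instance(3, 6)
        reached = {tuple(np.round(b, 12)) for b in reachable_beliefs(inst)}
        expected = _eq19_forward_expansion(inst, inst.initial_belief, 6)
        assert reached == expected

    def test_assumptions_enforced(self):
        with pytest.raises(Exception, match="all-off"):
            reachable_beliefs(compact_instance())


def _closed_loop_oracle(instance, belief, t):
    """Exhaustive expected-cost minimization over all closed-loop sensing
    refinements, using exact beliefs (no reachable-set machinery)."""
    if t >= instance.horizon:
        return 0.0
    t_mat = instance.transitions.matrix
    cm = instance.cost_matrix()
    omega = instance.omega
    p = belief @ t_mat
    rho_idle = float(p @ (p @ cm))
    idle_idx = instance.actions.index((0,) * instance.n_sensors)
    full_idx = instance.actions.index((1,) * instance.n_sensors)
    v_idle = (
        (1 - omega) * instance.actions.costs[idle_idx]
        + omega * rho_idle
        + _closed_loop_oracle(instance, p, t + 1)
    )
    v_sense = (1 - omega) * instance.actions.costs[full_idx] + sum(
        p[j] * _closed_loop_oracle(instance, np.eye(instance.n_states)[j], t + 1)
        for j in range(instance.n_states)
        if p[j] > 0
    )
    return min(v_idle, v_sense)


class TestExactDpAccurate:
    def test_matches_exhaustive_policy_enumeration(self):
        inst = _accurate_instance(2, 3)
        solution = exact_dp_accurate(inst)
        expected = _closed_loop_oracle(inst, inst.initial_belief.probs, 0)
        assert solution.optimal_value == pytest.approx(expected, abs=1e-12)

    def test_zero_sensing_cost_always_sense(self):
        inst = _accurate_instance(3, 5, sensor_cost=0.0)
        solution = exact_dp_accurate(inst)
        assert solution.optimal_value == pytest.approx(0.0)
        assert solution.action_for(inst.initial_belief, 0) == (1, 1, 1)

    def test_greedy_cost_dominates_exact_optimum(self, accurate_two_state_instance):
        """Myopic control can never beat the optimal DP in expectation."""
        inst = accurate_two_state_instance
        policy = GreedyPolicy(inst)
        t_mat = inst.transitions.matrix
        cm = inst.cost_matrix()
        omega = inst.omega

        def greedy_expected_cost(belief, t):
            if t >= inst.horizon:
                return 0.0
            action = policy.act(BeliefState(belief), epoch=t)
            idx = inst.actions.index(action)
            p = belief @ t_mat
            total = (1 - omega) * inst.actions.costs[idx]
            if action == (0, 0):
                return total + omega * float(p @ (p @ cm)) + greedy_expected_cost(p, t + 1)
            return total + sum(
                p[j] * greedy_expected_cost(np.eye(2)[j], t + 1)
                for j in range(2)
                if p[j] > 0
            )

        greedy_cost = greedy_expected_cost(inst.initial_belief.probs, 0)
        optimal = exact_dp_accurate(inst).optimal_value
        assert greedy_cost >= optimal - 1e-12
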