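"""Valuation models: softmax, TD updates, value-iteration sweep, hybrid mix."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navrl.gridworld import Action, RoomState, StepRecord, default_task
from navrl.learners import (
    TERMINAL,
    MBValues,
    ModelKind,
    ModelParams,
    compute_mb_values,
    hybrid_q,
    softmax_probs,
    td_update,
    zeros_q,
    zeros_trace,
)


class TestSoftmax:
    def test_equal_values_give_uniform(self):
        q = {a: 0.0 for a in Action}
        for theta in (1.0, 7.3, 15.0):
            p = softmax_probs(q, theta)
            assert all(abs(v - 0.25) < 1e-12 for v in p.values())

    def test_two_action_value(self):
        # p(a) = e^2 / (e^2 + 1) for q=(1,0), theta=2
        p = softmax_probs({Action.UP: 1.0, Action.DOWN: 0.0}, 2.0)
        assert p[Action.UP] == pytest.approx(math.exp(2) / (math.exp(2) + 1), abs=1e-12)
        assert p[Action.DOWN] == pytest.approx(1 / (math.exp(2) + 1), abs=1e-12)

    def test_monotone_in_theta(self):
        q = {Action.UP: 1.0, Action.DOWN: 0.0}
        probs = [softmax_probs(q, th)[Action.UP] for th in (1, 5, 10, 15)]
        assert all(a < b for a, b in zip(probs, probs[1:]))
        assert probs[-1] > 0.999

    def test_empty_action_set_raises(self):
        with pytest.raises(ValueError):
            softmax_probs({}, 5.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        qs=st.lists(st.floats(-5, 5), min_size=2, max_size=4),
        shift=st.floats(-100, 100),
        theta=st.floats(1, 15),
    )
    def test_shift_invariance_and_normalization(self, qs, shift, theta):
        actions = list(Action)[: len(qs)]
        p1 = softmax_probs(dict(zip(actions, qs)), theta)
        p2 = softmax_probs(dict(zip(actions, [q + shift for q in qs])), theta)
        assert abs(sum(p1.values()) - 1.0) < 1e-12
        for a in actions:
            assert p1[a] == pytest.approx(p2[a], abs=1e-9)
            assert p1[a] > 0


def _terminal_step(task):
    # (3,4) --down--> (4,4) = G3, rewarded
    return StepRecord(RoomState(3, 4), Action.DOWN, RoomState(4, 4), 1.0)


class TestTDUpdate:
    def test_td0_terminal_hand_example(self, task):
        """delta = 1 + 0 - 0 = 1; Q(s,a) <- 0 + 0.5 * 1."""
        params = ModelParams(ModelKind.TD0, alpha=0.5, theta=2.0)
        q, trace = zeros_q(task), zeros_trace(task.grid)
        td_update(params, q, trace, 2, _terminal_step(task), TERMINAL, task.grid)
        s = task.grid.index(RoomState(3, 4))
        assert q[2, s, Action.DOWN] == pytest.approx(0.5)
        assert np.count_nonzero(q) == 1

    @pytest.mark.parametrize("kind", [ModelKind.TD0, ModelKind.TD1, ModelKind.TDLAMBDA])
    def test_zero_learning_rate_is_inert(self, task, kind):
        params = ModelParams(kind, alpha=0.0, theta=2.0, lam=0.5)
        q, trace = zeros_q(task), zeros_trace(task.grid)
        td_update(params, q, trace, 2, _terminal_step(task), TERMINAL, task.grid)
        assert not q.any()

    def test_trace_decay_hand_example(self, task):
        """e(s,a) = lambda * 1 + 0 = 0.5 after a different pair is visited."""
        params = ModelParams(ModelKind.TDLAMBDA, alpha=0.1, theta=2.0, lam=0.5)
        q, trace = zeros_q(task), zeros_trace(task.grid)
        s1 = StepRecord(RoomState(2, 4), Action.DOWN, RoomState(3, 4), 0.0)
        td_update(params, q, trace, 2, s1, Action.DOWN, task.grid)
        td_update(params, q, trace, 2, _terminal_step(task), TERMINAL, task.grid)
        assert trace[task.grid.index(RoomState(2, 4)), Action.DOWN] == pytest.approx(0.5)
        assert trace[task.grid.index(RoomState(3, 4)), Action.DOWN] == pytest.approx(1.0)

    def test_terminal_without_reward_is_inconsistent(self, task):
        params = ModelParams(ModelKind.TD0, alpha=0.5, theta=2.0)
        q, trace = zeros_q(task), zeros_trace(task.grid)
        bad = StepRecord(RoomState(2, 4), Action.DOWN, RoomState(3, 4), 0.0)
        with pytest.raises(ValueError, match="TERMINAL"):
            td_update(params, q, trace, 2, bad, TERMINAL, task.grid)

    def test_td1_trace_is_binary_and_sticky(self, task):
        params = ModelParams(ModelKind.TD1, alpha=0.3, theta=2.0)
        q, trace = zeros_q(task), zeros_trace(task.grid)
        s1 = StepRecord(RoomState(2, 4), Action.DOWN, RoomState(3, 4), 0.0)
        for _ in range(3):  # revisits do not accumulate
            td_update(params, q, trace, 2, s1, Action.DOWN, task.grid)
        assert set(np.unique(trace)) <= {0.0, 1.0}


def _random_goal_walk(task, rng, goal_id="G3", max_len=60):
    """A random legal walk that stops on first goal entry (truncated otherwise)."""
    from navrl.gridworld import available_actions, step

    goal = task.goal_room(goal_id)
    room = RoomState(int(rng.integers(6)), int(rng.integers(6)))
    while room == goal:
        room = RoomState(int(rng.integers(6)), int(rng.integers(6)))
    start, actions = room, []
    for _ in range(max_len):
        a = list(available_actions(task.grid, room))[int(rng.integers(len(available_actions(task.grid, room))))]
        actions.append(a)
        room = step(task.grid, room, a)
        if room == goal:
            break
    from navrl.gridworld import build_trial

    truncated = room != goal
    return build_trial(task, "fixed", 0, goal_id, start, actions, truncated=truncated)


def test_tdlambda_at_zero_equals_td0_entrywise(task):
    """lambda = 0 collapses the trace to the current pair: identical Q at every step."""
    rng = np.random.default_rng(5)
    p0 = ModelParams(ModelKind.TD0, alpha=0.37, theta=3.0)
    pl = ModelParams(ModelKind.TDLAMBDA, alpha=0.37, theta=3.0, lam=0.0)
    q0, ql = zeros_q(task), zeros_q(task)
    for _ in range(30):
        trial = _random_goal_walk(task, rng)
        t0, tl = zeros_trace(task.grid), zeros_trace(task.grid)
        g = task.goal_index(trial.goal_id)
        for i, st_ in enumerate(trial.steps):
            nxt = (
                TERMINAL
                if st_.reward > 0
                else (trial.steps[i + 1].action if i + 1 < len(trial.steps) else None)
            )
            if nxt is None and st_.reward == 0:
                break  # truncated tail: no successor action
            td_update(p0, q0, t0, g, st_, nxt, task.grid)
            td_update(pl, ql, tl, g, st_, nxt, task.grid)
            np.testing.assert_array_equal(q0, ql)


def test_td0_values_stay_in_reward_range(task):
    """TD0 updates are convex moves toward targets in [0, r]: Q never escapes [0, 1]."""
    rng = np.random.default_rng(11)
    params = ModelParams(ModelKind.TD0, alpha=0.95, theta=3.0)
    q, _ = zeros_q(task), None
    for _ in range(40):
        trial = _random_goal_walk(task, rng)
        trace = zeros_trace(task.grid)
        g = task.goal_index(trial.goal_id)
        for i, st_ in enumerate(trial.steps):
            if st_.reward > 0:
                td_update(params, q, trace, g, st_, TERMINAL, task.grid)
            elif i + 1 < len(trial.steps):
                td_update(params, q, trace, g, st_, trial.steps[i + 1].action, task.grid)
        assert q.min() >= 0.0 and q.max() <= 1.0 + 1e-12


def test_tdlambda_trace_geometric_bound(task):
    """Accumulating trace with decay lambda is bounded by 1/(1-lambda)."""
    rng = np.random.default_rng(13)
    lam = 0.8
    params = ModelParams(ModelKind.TDLAMBDA, alpha=0.1, theta=3.0, lam=lam)
    q = zeros_q(task)
    for _ in range(20):
        trial = _random_goal_walk(task, rng)
        trace = zeros_trace(task.grid)
        g = task.goal_index(trial.goal_id)
        for i, st_ in enumerate(trial.steps):
            if st_.reward > 0:
                td_update(params, q, trace, g, st_, TERMINAL, task.grid)
            elif i + 1 < len(trial.steps):
                td_update(params, q, trace, g, st_, trial.steps[i + 1].action, task.grid)
            assert trace.min() >= 0.0
            assert trace.max() <= 1.0 / (1.0 - lam) + 1e-9


class TestModelBasedValues:
    def test_sweep_matches_gamma_power_distance(self, task, mb):
        """Converged value of an action = reward * gamma^(distance of landing room)."""
        import networkx as nx

        g = nx.grid_2d_graph(6, 6)
        from navrl.gridworld import available_actions, step

        for gi, (_, goal) in enumerate(task.goals):
            dist = nx.single_source_shortest_path_length(g, tuple(goal))
            for room in task.grid.states():
                for a in available_actions(task.grid, room):
                    landing = step(task.grid, room, a)
                    expected = 0.8 ** dist[tuple(landing)]
                    got = mb.values[gi, task.grid.index(room), int(a)]
                    assert got == pytest.approx(expected, abs=mb.tol)

    def test_goal_entering_action_is_worth_full_reward(self, task, mb):
        gi = task.goal_index("G3")
        s = task.grid.index(RoomState(3, 4))
        assert mb.values[gi, s, Action.DOWN] == pytest.approx(1.0, abs=1e-4)

    def test_gamma_zero_rewards_only_goal_entries(self, task):
        vals = compute_mb_values(task, gamma=0.0).values
        for gi, (_, goal) in enumerate(task.goals):
            from navrl.gridworld import available_actions, step

            for room in task.grid.states():
                for a in available_actions(task.grid, room):
                    expected = 1.0 if step(task.grid, room, a) == goal else 0.0
                    assert vals[gi, task.grid.index(room), int(a)] == pytest.approx(expected)

    def test_nonpositive_tolerance_rejected(self, task):
        with pytest.raises(ValueError):
            compute_mb_values(task, tol=0.0)

    def test_values_within_reward_range(self, mb):
        assert mb.values.min() >= 0.0
        assert mb.values.max() <= 1.0 + 1e-9


class TestHybrid:
    def test_endpoints(self, mb, task):
        q_mf = np.random.default_rng(2).random(mb.values.shape)
        np.testing.assert_array_equal(hybrid_q(q_mf, mb.values, 0.0), q_mf)
        np.testing.assert_array_equal(hybrid_q(q_mf, mb.values, 1.0), mb.values)

    def test_midpoint_value(self):
        assert hybrid_q(np.array([0.2]), np.array([0.6]), 0.5)[0] == pytest.approx(0.4)

    def test_shape_mismatch_raises(self, mb):
        with pytest.raises(ValueError, match="mismatch"):
            hybrid_q(np.zeros((2, 2)), mb.values, 0.5)


def test_params_bounds_enforced():
    with pytest.raises(ValueError):
        ModelParams(ModelKind.TD0, alpha=1.2, theta=5.0)
    with pytest.raises(ValueError):
        ModelParams(ModelKind.MB, theta=0.5)
    # lam irrelevant to TD0: out-of-range value is ignored, not validated
    ModelParams(ModelKind.TD0, alpha=0.5, theta=5.0, lam=7.0)


def test_free_parameter_counts():
    ks = {
        ModelKind.TD0: 2,
        ModelKind.TD1: 2,
        ModelKind.TDLAMBDA: 3,
        ModelKind.MB: 1,
        ModelKind.HYBRID: 4,
    }
    for kind, k in ks.items():
        assert ModelParams(kind, alpha=0.5, theta=5.0, lam=0.5, omega=0.5).k == k
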