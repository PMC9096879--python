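"""Agent state space, policy, learning rules, and the batch engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sixarm.agents import (
    MODELS,
    N_STATES,
    N_UNREACHABLE_STATES,
    AgentState,
    ModelParams,
    ModelSpec,
    PropensitySet,
    action_probabilities,
    apply_updates,
    enumerate_states,
    force_trajectory,
    prediction_error,
    run_agent,
    state_from_index,
    state_index,
    total_propensity,
)
from sixarm.task import REST, Contingency, Schedule, TaskState, alternation_step


class TestStateSpace:
    def test_exactly_43_states_and_bijection(self):
        pairs = enumerate_states()
        assert len(pairs) == N_STATES == 43
        assert len(set(pairs)) == 43
        for i, (p, c) in enumerate(pairs):
            assert state_index(p, c) == i
            assert state_from_index(i) == (p, c)

    def test_start_state_and_same_arm_pairs(self):
        assert state_index(REST, REST) == 42
        # same-arm pairs are indexable even though play never produces them
        diag = [state_index(a, a) for a in range(1, 7)]
        assert len(diag) == N_UNREACHABLE_STATES == 6

    def test_rest_as_current_only_in_start_state(self):
        with pytest.raises(ValueError):
            state_index(3, REST)

    def test_same_arm_states_never_visited_in_play(self, tiny_schedule, mid_params):
        res = run_agent("M3", mid_params, tiny_schedule, n_repeats=5, seed=11)
        valid = res.arms >= 0
        assert np.all(res.arms[valid] != res.prev[valid])


class TestPropensities:
    def test_m1_all_zero(self):
        m = total_propensity(MODELS["M1"], PropensitySet.zeros(), AgentState(2, 3))
        assert np.array_equal(m, np.zeros(6))

    def test_neighbor_term_midtrack(self):
        pset = PropensitySet.zeros()
        pset.b_n1 = 1.0
        m = total_propensity(MODELS["M3"], pset, AgentState(REST, 3))
        assert np.array_equal(m, [0, 1, 0, 1, 0, 0])

    def test_neighbor_term_clipped_at_edge(self):
        pset = PropensitySet.zeros()
        pset.b_n1 = 1.0
        m = total_propensity(MODELS["M3"], pset, AgentState(REST, 1))
        assert np.array_equal(m, [0, 1, 0, 0, 0, 0])

    def test_two_away_term(self):
        pset = PropensitySet.zeros()
        pset.b_n2 = 2.0
        m = total_propensity(MODELS["M3"], pset, AgentState(REST, 5))
        assert np.array_equal(m, [0, 0, 2, 0, 0, 0])

    def test_variant_flags(self):
        pset = PropensitySet.zeros()
        pset.b_arm[:] = 1.0
        pset.b_n1 = 5.0
        s = AgentState(2, 3)
        assert np.array_equal(total_propensity(MODELS["M1"], pset, s), np.zeros(6))
        assert np.array_equal(total_propensity(MODELS["M2"], pset, s), np.ones(6))
        m3noarm = total_propensity(MODELS["M3noArm"], pset, s)
        assert np.array_equal(m3noarm, [0, 5, 0, 5, 0, 0])


class TestActionProbabilities:
    def test_uniform(self):
        p = action_probabilities(np.zeros(6), cur_arm=6)
        assert np.allclose(p, [0.2, 0.2, 0.2, 0.2, 0.2, 0.0])

    def test_hand_softmax(self):
        m = np.array([0, 0, np.log(2), 0, 0, 0])
        p = action_probabilities(m, cur_arm=6)
        assert np.allclose(p, [1 / 6, 1 / 6, 1 / 3, 1 / 6, 1 / 6, 0.0])

    def test_rest_box_allows_all_six(self):
        p = action_probabilities(np.zeros(6), cur_arm=REST)
        assert np.allclose(p, np.full(6, 1 / 6))

    @settings(deadline=None, max_examples=60)
    @given(
        m=st.lists(st.floats(-30, 30), min_size=6, max_size=6),
        cur=st.integers(1, 6),
        shift=st.floats(-50, 50),
    )
    def test_normalization_and_shift_invariance(self, m, cur, shift):
        m = np.array(m)
        p = action_probabilities(m, cur)
        assert p[cur - 1] == 0.0
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)
        p2 = action_probabilities(m + shift, cur)
        assert np.allclose(p, p2, atol=1e-12)


class TestPredictionError:
    @pytest.mark.parametrize(
        "r,vt,vt1,gamma,expected",
        [(1, 0, 0, 0.9, 1.0), (0, 0.1, 0.4, 0.5, 0.1), (1, 2.0, 2.0, 0.5, 0.0)],
    )
    def test_examples(self, r, vt, vt1, gamma, expected):
        if expected == 0.0:
            # fixed point: r + gamma*v - v = 0 when v = r/(1-gamma)
            assert prediction_error(r, r / (1 - gamma), r / (1 - gamma), gamma) == pytest.approx(0)
        else:
            assert prediction_error(r, vt, vt1, gamma) == pytest.approx(expected)


def _random_pset(rng) -> PropensitySet:
    return PropensitySet(
        b_trans=rng.normal(size=(6, N_STATES)),
        b_arm=rng.normal(size=6),
        b_n1=rng.normal(),
        b_n2=rng.normal(),
        v=rng.normal(size=N_STATES),
    )


class TestApplyUpdates:
    def test_no_signal_no_decay_is_identity(self, rng):
        pset = _random_pset(rng)
        s = AgentState(2, 3)
        probs = action_probabilities(total_propensity(MODELS["M3"], pset, s), 3)
        out = apply_updates(
            MODELS["M3"], pset, s, 4, probs, delta=0.0,
            params=ModelParams(alpha=0.5, gamma=0.5, omega=0.0),
        )
        assert out.allclose(pset, atol=0)

    def test_pure_decay_scales_everything(self, rng):
        pset = _random_pset(rng)
        s = AgentState(2, 3)
        probs = action_probabilities(np.zeros(6), 3)
        out = apply_updates(
            MODELS["M3"], pset, s, 4, probs, delta=0.0,
            params=ModelParams(alpha=0.5, gamma=0.5, omega=0.01),
        )
        assert np.allclose(out.b_trans, pset.b_trans * 0.99)
        assert np.allclose(out.b_arm, pset.b_arm * 0.99)
        assert out.b_n1 == pytest.approx(pset.b_n1 * 0.99)
        assert np.allclose(out.v, pset.v * 0.99)

    @pytest.mark.parametrize("choice", [1, 2, 4, 5, 6])
    def test_reinforce_increments_sum_to_zero(self, rng, choice):
        """The policy-gradient increment (1-p) on the chosen arm and -p on
        the rest cancels across arms, for the state column and for b_arm."""
        pset = _random_pset(rng)
        s = AgentState(2, 3)
        probs = action_probabilities(total_propensity(MODELS["M3"], pset, s), 3)
        out = apply_updates(
            MODELS["M3"], pset, s, choice, probs, delta=0.7,
            params=ModelParams(alpha=0.3, gamma=0.5, omega=0.0),
        )
        dcol = out.b_trans[:, s.index] - pset.b_trans[:, s.index]
        assert abs(dcol.sum()) < 1e-12
        darm = out.b_arm - pset.b_arm
        assert abs(darm.sum()) < 1e-12
        # only the visited state's column changes when omega = 0
        other = np.delete(out.b_trans - pset.b_trans, s.index, axis=1)
        assert np.all(other == 0)

    def test_neighbor_update_uses_summed_probability_mass(self, rng):
        pset = PropensitySet.zeros()
        s = AgentState(2, 3)  # neighbors of arm 3 are arms 2 and 4
        probs = action_probabilities(np.zeros(6), 3)
        alpha, delta = 0.5, 1.0
        out = apply_updates(
            MODELS["M3"], pset, s, 4, probs, delta,
            params=ModelParams(alpha=alpha, gamma=0.5, omega=0.0),
        )
        p_mass1 = probs[1] + probs[3]  # arms 2 and 4
        assert out.b_n1 == pytest.approx(alpha * delta * (1 - p_mass1))
        p_mass2 = probs[0] + probs[4]  # arms 1 and 5
        assert out.b_n2 == pytest.approx(alpha * delta * (0 - p_mass2))

    def test_zero_alpha_decays_geometrically_to_indifference(self, rng):
        pset = _random_pset(rng)
        params = ModelParams(alpha=0.0, gamma=0.5, omega=0.01)
        s = AgentState(2, 3)
        probs = action_probabilities(np.zeros(6), 3)
        cur = pset
        for _ in range(50):
            cur = apply_updates(MODELS["M3"], cur, s, 4, probs, 1.0, params)
        assert np.allclose(cur.b_trans, pset.b_trans * 0.99**50)
        assert np.allclose(cur.v, pset.v * 0.99**50)


def scalar_episode(spec, params, schedule, seed):
    """Independent scalar oracle: the agent loop written directly on the
    reference operations and the task rules, consuming one uniform per trial
    exactly as the batch engine does."""
    rng = np.random.default_rng(seed)
    pset = PropensitySet.zeros()
    arms_out, rew_out = [], []
    for phase in schedule.phases:
        for limit in phase.session_limits:
            prev, cur = REST, REST
            n_rewards = 0
            task = TaskState.fresh(phase.contingency) if phase.kind == "alt" else None
            while True:
                state = AgentState(prev, cur)
                probs = action_probabilities(
                    total_propensity(spec, pset, state), cur
                )
                u = rng.random()
                cum = np.cumsum(probs)
                cum[-1] = 1.0
                choice = int(np.argmax(cum > u)) + 1
                if phase.kind == "alt":
                    rewarded, task = alternation_step(task, choice)
                else:
                    rewarded = choice != cur
                delta = prediction_error(
                    float(rewarded),
                    pset.v[state.index],
                    pset.v[AgentState(cur, choice).index],
                    params.gamma,
                )
                pset = apply_updates(spec, pset, state, choice, probs, delta, params)
                arms_out.append(choice)
                rew_out.append(int(rewarded))
                n_rewards += rewarded
                prev, cur = cur, choice
                if phase.kind == "alt":
                    if task.center_visits >= limit and choice != phase.contingency.center:
                        break
                else:
                    if n_rewards >= limit:
                        break
    return np.array(arms_out), np.array(rew_out), pset


class TestEngineAgainstScalarOracle:
    @pytest.mark.parametrize("model", ["M1", "M2", "M3", "M3noArm"])
    def test_batch_engine_matches_scalar_loop(self, model, tiny_schedule):
        params = ModelParams(alpha=0.5, gamma=0.6, omega=0.008)
        seed = 77
        arms_o, rew_o, pset_o = scalar_episode(
            MODELS[model], params, tiny_schedule, seed
        )
        res = run_agent(model, params, tiny_schedule, n_repeats=1, seed=seed)
        n = int(res.lengths[0])
        assert np.array_equal(res.arms[0, :n], arms_o)
        assert np.array_equal(res.rewarded[0, :n], rew_o)
        assert res.propensities(0).allclose(pset_o, atol=1e-9)


class TestRunAgent:
    def test_same_seed_identical(self, tiny_schedule, mid_params):
        a = run_agent("M3", mid_params, tiny_schedule, n_repeats=4, seed=5)
        b = run_agent("M3", mid_params, tiny_schedule, n_repeats=4, seed=5)
        assert np.array_equal(a.arms, b.arms)
        assert np.array_equal(a.rewarded, b.rewarded)

    def test_batch_repeat_equals_single_run(self, tiny_schedule, mid_params):
        batch = run_agent("M2", mid_params, tiny_schedule, n_repeats=3, seed=40)
        for k in range(3):
            single = run_agent("M2", mid_params, tiny_schedule, n_repeats=1, seed=40 + k)
            n = int(single.lengths[0])
            assert n == batch.lengths[k]
            assert np.array_equal(single.arms[0, :n], batch.arms[k, :n])

    def test_nesting_with_static_propensities(self, tiny_schedule):
        """With learning off, M3 started at zero neighbor preferences makes
        exactly the same choices as M2, and M2 with zero arm preferences the
        same as M1: the richer models nest the simpler ones."""
        params = ModelParams(alpha=0.0, gamma=0.5, omega=0.0)
        rng = np.random.default_rng(0)
        init = PropensitySet.zeros()
        init.b_trans = rng.normal(size=(6, N_STATES))
        init.b_arm = rng.normal(size=6)
        from sixarm._engine import run_batch

        m3 = run_batch(MODELS["M3"], params, tiny_schedule, 2, seed=9, init=init)
        m2 = run_batch(MODELS["M2"], params, tiny_schedule, 2, seed=9, init=init)
        assert np.array_equal(m3.arms, m2.arms)

        init2 = init.copy()
        init2.b_arm[:] = 0.0
        m2b = run_batch(MODELS["M2"], params, tiny_schedule, 2, seed=9, init=init2)
        m1 = run_batch(MODELS["M1"], params, tiny_schedule, 2, seed=9, init=init2)
        assert np.array_equal(m2b.arms, m1.arms)

    def test_trajectory_frame_shape(self, tiny_schedule, mid_params):
        res = run_agent("M3", mid_params, tiny_schedule, n_repeats=1, seed=2)
        df = res.trajectory(0, "r0")
        assert list(df.columns) == [
            "rat_id", "phase", "contingency_label", "session", "trial",
            "arm", "rewarded",
        ]
        assert df["arm"].between(1, 6).all()
        assert set(df["phase"]) == {"explore", "alt"}
        # trial numbering restarts at 1 in every session
        assert (df.groupby("session")["trial"].first() == 1).all()


class TestForceTrajectory:
    def test_empty_is_identity(self, mid_params):
        pset = PropensitySet.zeros()
        out = force_trajectory("M3", mid_params, [], pset)
        assert out.allclose(pset)

    def test_neighbor_rich_trajectory_raises_bn1(self, mid_params):
        sessions = [[1, 2, 3, 4, 5, 6, 5, 4, 3, 2] * 4] * 3
        out = force_trajectory("M3", mid_params, sessions)
        assert out.b_n1 > 0

    def test_forcing_consumes_no_randomness_and_is_deterministic(self, mid_params):
        sessions = [[1, 3, 5, 2, 6, 4] * 5]
        a = force_trajectory("M3", mid_params, sessions)
        b = force_trajectory("M3", mid_params, sessions)
        assert a.allclose(b, atol=0)

    def test_illegal_repeat_raises(self, mid_params):
        with pytest.raises(ValueError):
            force_trajectory("M3", mid_params, [[1, 1]])
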