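"""Behavioral metrics: preferences, sweeps, direction alternation, curves."""

import numpy as np
import pandas as pd
import pytest

from sixarm.metrics import (
    contingency_blocks,
    direction_alternation_rate,
    large_sweep_rate,
    performance_curves,
    preference_stats,
    smooth_gaussian,
)


class TestPreferenceStats:
    def test_monotone_sweep(self):
        st = preference_stats([1, 2, 3, 4, 5, 6])
        assert st.neighbor_freq == 1.0
        assert st.inertia == 1.0

    def test_strict_zigzag(self):
        st = preference_stats([1, 2, 1, 2, 1])
        assert st.neighbor_freq == 1.0
        assert st.inertia == 0.0

    def test_two_away_conditional(self):
        st = preference_stats([1, 3, 5, 2])
        assert st.neighbor_freq == 0.0
        assert st.two_away_given_not_neighbor == pytest.approx(2 / 3)

    def test_arm_probs_and_transition_matrix(self):
        st = preference_stats([1, 2, 1, 2, 3])
        assert np.allclose(st.arm_probs, [2 / 5, 2 / 5, 1 / 5, 0, 0, 0])
        assert st.max_arm_prob == pytest.approx(2 / 5)
        assert st.transition_matrix[0] == pytest.approx(
            [0, 1, 0, 0, 0, 0]
        )  # arm 1 always went to arm 2
        assert st.transition_matrix[1] == pytest.approx([0.5, 0, 0.5, 0, 0, 0])

    def test_transitions_break_at_session_boundaries(self):
        joined = preference_stats([[1, 2], [6, 5]])
        assert joined.n_transitions == 2  # not 3: no 2 -> 6 jump
        assert joined.neighbor_freq == 1.0

    def test_needs_two_visits(self):
        with pytest.raises(ValueError):
            preference_stats([3])

    def test_markov_chain_law_of_large_numbers(self, rng):
        """On a long chain with known transition matrix the empirical
        statistics converge to the chain's stationary quantities."""
        P = np.array(
            [
                [0.0, 0.5, 0.2, 0.1, 0.1, 0.1],
                [0.3, 0.0, 0.3, 0.2, 0.1, 0.1],
                [0.1, 0.4, 0.0, 0.3, 0.1, 0.1],
                [0.1, 0.1, 0.4, 0.0, 0.3, 0.1],
                [0.1, 0.1, 0.2, 0.3, 0.0, 0.3],
                [0.1, 0.1, 0.1, 0.2, 0.5, 0.0],
            ]
        )
        n = 10_000
        arms = np.empty(n, dtype=int)
        arms[0] = 1
        for i in range(1, n):
            arms[i] = rng.choice(6, p=P[arms[i - 1] - 1]) + 1
        st = preference_stats(arms)

        # stationary distribution of the chain (left eigenvector)
        w, vl = np.linalg.eig(P.T)
        pi = np.real(vl[:, np.argmin(np.abs(w - 1))])
        pi /= pi.sum()
        se = np.sqrt(pi * (1 - pi) / n)
        assert np.all(np.abs(st.arm_probs - pi) < 3 * se + 1e-9)

        nb_mask = np.abs(np.subtract.outer(np.arange(6), np.arange(6))) == 1
        nb_expected = float(np.sum(pi[:, None] * P * nb_mask))
        se_nb = np.sqrt(nb_expected * (1 - nb_expected) / n)
        assert abs(st.neighbor_freq - nb_expected) < 3 * se_nb

        # inertia: expectation over stationary transition pairs
        num = 0.0
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    if np.sign(j - i) == np.sign(k - j):
                        num += pi[i] * P[i, j] * P[j, k]
        se_in = np.sqrt(num * (1 - num) / n)
        assert abs(st.inertia - num) < 3 * se_in

    def test_reflection_symmetry(self, rng):
        arms = rng.integers(1, 7, size=500)
        arms = arms[np.insert(np.diff(arms) != 0, 0, True)]  # drop repeats
        st = preference_stats(arms)
        st_r = preference_stats(7 - arms)
        assert st.max_arm_prob == pytest.approx(st_r.max_arm_prob)
        assert st.neighbor_freq == pytest.approx(st_r.neighbor_freq)
        assert st.inertia == pytest.approx(st_r.inertia)
        assert st.two_away_given_not_neighbor == pytest.approx(
            st_r.two_away_given_not_neighbor
        )
        assert large_sweep_rate(arms) == pytest.approx(large_sweep_rate(7 - arms))


class TestLargeSweepRate:
    def test_full_sweep(self):
        assert large_sweep_rate([1, 2, 3, 4, 5]) == 1.0

    def test_zigzag_has_no_large_sweeps(self):
        assert large_sweep_rate([1, 2, 1, 2, 1]) == 0.0

    def test_pivot_belongs_to_terminated_run(self):
        # run 1-2-3-4 spans four arms (counted); 4->2->3 pieces span <= 3
        assert large_sweep_rate([1, 2, 3, 4, 2, 3]) == pytest.approx(4 / 6)

    def test_span_is_arms_covered_not_visit_count(self):
        # 2-4-6 is three visits but spans five arms
        assert large_sweep_rate([2, 4, 6]) == 1.0
        assert large_sweep_rate([2, 4, 6], span_threshold=5) == 0.0

    def test_threshold_boundary(self):
        # span exactly 3 ("three arms") is not a large sweep
        assert large_sweep_rate([1, 2, 3]) == 0.0
        assert large_sweep_rate([1, 2, 3, 4]) == 1.0


class TestDirectionAlternation:
    def test_perfect_alternation_sequence(self):
        da = direction_alternation_rate([3, 4, 3, 2, 3, 4], smooth_sd=0)
        assert da.rate == 1.0

    def test_monotone_sweep_never_alternates(self):
        assert direction_alternation_rate([1, 2, 3, 4, 5, 6], smooth_sd=0).rate == 0.0

    def test_zigzag_never_alternates(self):
        assert direction_alternation_rate([1, 2, 1, 2, 1], smooth_sd=0).rate == 0.0

    def test_needs_three_transitions(self):
        with pytest.raises(ValueError):
            direction_alternation_rate([1, 2, 3])


class TestSmoothing:
    def test_zero_sd_is_identity(self, rng):
        x = rng.random(50)
        assert np.array_equal(smooth_gaussian(x, 0.0), x)

    def test_convex_combination_preserves_range(self, rng):
        x = rng.random(200)
        sm = smooth_gaussian(x, 10.0)
        assert sm.min() >= x.min() - 1e-12
        assert sm.max() <= x.max() + 1e-12

    def test_constant_series_unchanged(self):
        x = np.full(30, 0.4)
        assert np.allclose(smooth_gaussian(x, 5.0), x)

    def test_kernel_mass_renormalized_at_edges(self):
        x = np.ones(20)
        sm = smooth_gaussian(x, 4.0)
        assert np.allclose(sm, 1.0)  # no mass leaks off the edges


def _block_frame(arms, rewarded, label="234", session=0):
    return pd.DataFrame(
        {
            "rat_id": "r",
            "phase": "alt",
            "contingency_label": label,
            "session": session,
            "trial": np.arange(1, len(arms) + 1),
            "arm": arms,
            "rewarded": rewarded,
        }
    )


class TestPerformanceCurves:
    def test_all_rewarded(self):
        arms = [3, 4, 3, 2, 3, 4, 3, 2]
        block = _block_frame(arms, [1] * len(arms))
        pc = performance_curves(block)
        assert np.allclose(pc.reward_prob, 1.0)
        assert pc.trials_to_75 == 1

    def test_never_rewarded(self):
        arms = [1, 5, 1, 5, 1, 5]
        block = _block_frame(arms, [0] * len(arms))
        pc = performance_curves(block)
        assert pc.trials_to_75 is None

    def test_step_crossing_with_narrow_smoother(self):
        arms = [3, 4] * 10
        rewarded = [0] * 10 + [1] * 10
        pc = performance_curves(_block_frame(arms, rewarded), smooth_sd=1e-9)
        assert pc.trials_to_75 == 11

    def test_trial_types_split_inbound_outbound(self):
        # outbound trials start at the center (arm 3)
        arms = [3, 4, 3, 2, 3]
        rewarded = [1, 1, 1, 0, 1]
        pc = performance_curves(_block_frame(arms, rewarded))
        # first visit starts from the rest box: neither inbound nor outbound
        assert len(pc.outbound_err_trials) == 2  # from-3 trials: visits 2 and 4
        assert len(pc.inbound_err_trials) == 2  # from-4 and from-2 trials
        assert pc.outbound_err_trials.tolist() == [0.0, 1.0]

    def test_empty_block_raises(self):
        with pytest.raises(ValueError):
            performance_curves(_block_frame([], []))


class TestContingencyBlocks:
    def test_repeated_labels_split_by_contiguity(self):
        frames = []
        sess = 0
        for label in ("234", "123", "234"):
            frames.append(_block_frame([3, 4, 3], [1, 1, 1], label, session=sess))
            sess += 1
        df = pd.concat(frames, ignore_index=True)
        blocks = contingency_blocks(df)
        assert [l for l, _ in blocks] == ["234", "123", "234"]
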