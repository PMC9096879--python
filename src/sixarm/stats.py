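"""Monte-Carlo and permutation inference for exploratory preferences and model
comparison.

Three kinds of machinery live here:

* per-animal Monte-Carlo null tests for exploratory preference statistics,
  with nulls of increasing specificity (uniform arm choice, the animal's own
  arm-visit probabilities, the animal's own transition probabilities);
* a population-level randomness test that aggregates per-animal evidence
  ``phi_i = p(data | random)`` into a frequentist test of "half the
  population behaves randomly" against "fewer than half do", evaluated by
  Monte-Carlo classification of each animal and the fair-binomial lower
  tail;
* permutation tests: paired sign-flip tests, the learning-speed
  (75%-crossing) label-permutation test between two sets of model repeats,
  rank-order variance explained, and median-split group comparison.

All Monte-Carlo p-values are floored at the resolution of the sampling
(1/n draws, or 1/(n+1) with add-one smoothing for permutation tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from sixarm.metrics import crossing_index, smooth_gaussian

#: Bonferroni-corrected significance threshold for the three exploratory
#: preference tests (max arm probability, neighbor frequency, inertia).
PREFERENCE_ALPHA = 0.05 / 3


# ---------------------------------------------------------------------------
# Monte-Carlo nulls for preference statistics
# ---------------------------------------------------------------------------

def mc_null_p(
    observed: float,
    null_sampler: Callable[[np.random.Generator, int], np.ndarray],
    n_draws: int = 10_000,
    seed: int = 0,
) -> float:
    """One-sided Monte-Carlo p-value: fraction of null draws >= observed.

    ``null_sampler(rng, n)`` must return ``n`` draws of the statistic under
    the null.  The p-value is floored at ``1/n_draws`` (an observed value
    above every draw cannot be claimed rarer than the sampling resolution).
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    draws = np.asarray(null_sampler(rng, n_draws), dtype=float)
    if draws.shape != (n_draws,):
        raise ValueError("null_sampler must return n_draws values")
    p = float(np.mean(draws >= observed))
    return max(p, 1.0 / n_draws)


def _session_lengths(sessions: Sequence[np.ndarray]) -> list[int]:
    return [len(s) for s in sessions]


def null_max_arm_prob(sessions: Sequence[np.ndarray]):
    """Null sampler: maximum arm-visit probability under uniform random choice.

    Visit counts match the animal's sessions; arms are drawn iid uniform
    over the six arms.
    """
    n_visits = sum(_session_lengths(sessions))

    def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
        draws = rng.integers(0, 6, size=(n, n_visits))
        counts = np.stack([(draws == a).sum(axis=1) for a in range(6)], axis=1)
        return counts.max(axis=1) / n_visits

    return sampler


def null_neighbor_freq(sessions: Sequence[np.ndarray]):
    """Null sampler: neighbor-transition frequency given the animal's own
    arm-visit probabilities (visits drawn iid from them, per session)."""
    arms_all = np.concatenate([np.asarray(s, dtype=int) for s in sessions])
    probs = np.bincount(arms_all, minlength=7)[1:7] / arms_all.size
    lengths = _session_lengths(sessions)

    def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
        nb = np.zeros(n)
        tot = 0
        for ln in lengths:
            if ln < 2:
                continue
            draws = rng.choice(np.arange(1, 7), size=(n, ln), p=probs)
            d = np.abs(np.diff(draws, axis=1))
            nb += (d == 1).sum(axis=1)
            tot += ln - 1
        return nb / tot

    return sampler


def null_inertia(sessions: Sequence[np.ndarray]):
    """Null sampler: directional inertia given the animal's own transition
    probabilities (first-order Markov chains started from each session's
    actual first arm)."""
    counts = np.zeros((6, 6))
    starts = []
    lengths = []
    for s in sessions:
        s = np.asarray(s, dtype=int)
        if len(s) < 2:
            continue
        np.add.at(counts, (s[:-1] - 1, s[1:] - 1), 1)
        starts.append(s[0])
        lengths.append(len(s))
    row = counts.sum(axis=1, keepdims=True)
    # rows never visited fall back to uniform over the other five arms
    fallback = (1.0 - np.eye(6)) / 5.0
    tmat = np.where(row > 0, counts / np.where(row > 0, row, 1), fallback)
    tcum = np.cumsum(tmat, axis=1)
    tcum[:, -1] = 1.0

    def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
        same = np.zeros(n)
        tot = 0
        for start, ln in zip(starts, lengths):
            cur = np.full(n, start - 1)
            prev_sign = np.zeros(n)
            for step in range(ln - 1):
                u = rng.random(n)
                nxt = (tcum[cur] > u[:, None]).argmax(axis=1)
                sign = np.sign(nxt - cur)
                if step > 0:
                    same += sign == prev_sign
                prev_sign = sign
                cur = nxt
            tot += max(ln - 2, 0)
        return same / tot

    return sampler


# ---------------------------------------------------------------------------
# Population randomness test
# ---------------------------------------------------------------------------

@dataclass
class RandomnessEvidence:
    """Per-animal probabilities of the data under the random-behavior null."""

    phi: np.ndarray  # (N,) p(data | random) per animal
    stat_name: str = ""
    n_null_draws: int = 10_000

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.size == 0:
            raise ValueError("need at least one animal")
        if np.any(self.phi < 0) or np.any(self.phi > 1):
            raise ValueError("phi entries must be in [0, 1]")


def _binom_lower_tail(n_animals: int) -> np.ndarray:
    """Fair-binomial lower-tail table: entry m is sum_{k<=m} C(N,k)/2^N."""
    return sps.binom.cdf(np.arange(n_animals + 1), n_animals, 0.5)


def population_randomness_test(
    ev: RandomnessEvidence, n_samples: int = 100_000, seed: int = 0
) -> float:
    """Probability that at least half the population behaves randomly.

    Each Monte-Carlo sample classifies every animal as random independently
    with probability ``phi_i``; with ``m`` animals classified random, the
    sample contributes the fair-binomial lower tail ``P(Binom(N, 1/2) <= m)``.
    The returned p-value is the average tail over samples — small when the
    per-animal evidence says almost nobody is random.
    """
    rng = np.random.default_rng(seed)
    phi = ev.phi
    n_animals = phi.size
    tails = _binom_lower_tail(n_animals)
    total = 0.0
    done = 0
    while done < n_samples:  # chunked so large sample counts stay in memory
        chunk = min(n_samples - done, 200_000)
        m = (rng.random((chunk, n_animals)) < phi[None, :]).sum(axis=1)
        total += float(tails[m].sum())
        done += chunk
    return total / n_samples


def population_randomness_exact(ev: RandomnessEvidence) -> float:
    """Exact version of :func:`population_randomness_test`.

    Computes the Poisson-binomial distribution of the number of random
    animals by dynamic programming and sums it against the fair-binomial
    lower tail.  Feasible for any N; used as the oracle for the sampled
    version.
    """
    phi = ev.phi
    n_animals = phi.size
    pmf = np.zeros(n_animals + 1)
    pmf[0] = 1.0
    for p in phi:
        pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= 1 - p
    return float(pmf @ _binom_lower_tail(n_animals))


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def paired_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perms: int = 10_000,
    seed: int = 0,
    tail: str = "two",
) -> float:
    """Sign-flip permutation test on paired differences (statistic: mean).

    ``tail`` is ``"two"``, ``"greater"`` (x > y) or ``"less"``.  The p-value
    uses add-one smoothing, flooring it at ``1/(n_perms + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    d = x - y
    obs = d.mean()
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perms, d.size)) * 2 - 1
    perm = (signs * d[None, :]).mean(axis=1)
    if tail == "greater":
        extreme = perm >= obs
    elif tail == "less":
        extreme = perm <= obs
    elif tail == "two":
        extreme = np.abs(perm) >= abs(obs)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (int(extreme.sum()) + 1) / (n_perms + 1)


def crossing_permutation_test(
    repeats_a: Sequence[np.ndarray],
    repeats_b: Sequence[np.ndarray],
    animal_curves: Sequence[np.ndarray],
    n_perms: int = 10_000,
    seed: int = 0,
    threshold: float = 0.75,
    smooth_sd: float = 10.0,
    tail: str = "greater",
) -> tuple[float, float]:
    """Label-permutation test of which model's average crosses 75% closer to the animals.

    For each contingency ``c``, ``repeats_a[c]`` and ``repeats_b[c]`` are
    per-repeat reward-indicator curves (``(n_repeats, T_c)``), and
    ``animal_curves[c]`` is the averaged animal reward curve.  The statistic
    is ``delta_d = d_A - d_B`` where ``d`` averages, over contingencies, the
    difference between the model-average 75%-crossing trial and the animal
    crossing trial.  Repeat labels are permuted jointly across contingencies.
    An average that never crosses is censored at its final trial + 1.

    Returns ``(p, delta_d_true)``.  With ``tail="greater"`` small p means
    model A crosses reliably later (relative to the animals) than model B.
    """
    n_cont = len(repeats_a)
    if not (n_cont == len(repeats_b) == len(animal_curves)):
        raise ValueError("inputs must cover the same contingencies")
    n_a = repeats_a[0].shape[0]
    n_b = repeats_b[0].shape[0]
    n_tot = n_a + n_b

    # Smooth per-repeat curves once; group means of smoothed curves equal
    # smoothed group means because the smoother is linear.
    smoothed = []
    animal_cross = []
    for c in range(n_cont):
        stack = np.vstack([repeats_a[c], repeats_b[c]]).astype(float)
        smoothed.append(np.apply_along_axis(smooth_gaussian, 1, stack, smooth_sd))
        ac = crossing_index(smooth_gaussian(np.asarray(animal_curves[c], float), smooth_sd), threshold)
        animal_cross.append(ac if ac is not None else len(animal_curves[c]) + 1)

    def censored_crossing(curve: np.ndarray) -> float:
        ci = crossing_index(curve, threshold)
        return float(ci) if ci is not None else float(len(curve) + 1)

    def delta_d(idx_a: np.ndarray, idx_b: np.ndarray) -> float:
        d_a = d_b = 0.0
        for c in range(n_cont):
            mean_a = smoothed[c][idx_a].mean(axis=0)
            mean_b = smoothed[c][idx_b].mean(axis=0)
            d_a += censored_crossing(mean_a) - animal_cross[c]
            d_b += censored_crossing(mean_b) - animal_cross[c]
        return (d_a - d_b) / n_cont

    idx = np.arange(n_tot)
    obs = delta_d(idx[:n_a], idx[n_a:])
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perms)
    for i in range(n_perms):
        perm = rng.permutation(n_tot)
        perm_stats[i] = delta_d(perm[:n_a], perm[n_a:])
    if tail == "greater":
        extreme = perm_stats >= obs
    elif tail == "less":
        extreme = perm_stats <= obs
    else:
        raise ValueError("tail must be 'greater' or 'less'")
    p = (int(extreme.sum()) + 1) / (n_perms + 1)
    return p, obs


def rank_order_r2(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Variance in one ordering explained by the other (squared Spearman r).

    Ties receive average ranks.  Identical and exactly reversed orderings
    both give 1.0 (a perfect linear rank relation, of either sign).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    r = np.corrcoef(ra, rb)[0, 1]
    return float(r**2)


@dataclass
class MedianSplitResult:
    high_idx: np.ndarray
    low_idx: np.ndarray
    high_mean: float
    low_mean: float
    p: float


def median_split_compare(scores: np.ndarray, outcomes: np.ndarray) -> MedianSplitResult:
    """Split animals at the median score and rank-sum-test their outcomes.

    The split depends only on the ranks of ``scores`` (invariant to monotone
    transforms); with an odd number of animals the middle animal joins the
    low group.  Outcomes are compared across groups with the Wilcoxon
    rank-sum test.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if scores.shape != outcomes.shape or scores.ndim != 1 or scores.size < 4:
        raise ValueError("need at least 4 paired scores/outcomes")
    if np.all(scores == scores[0]):
        raise ValueError("median split undefined: all scores equal")
    order = np.argsort(scores, kind="stable")
    n_low = scores.size // 2 + scores.size % 2
    low_idx = np.sort(order[:n_low])
    high_idx = np.sort(order[n_low:])
    hi, lo = outcomes[high_idx], outcomes[low_idx]
    pooled = np.concatenate([hi, lo])
    if np.all(pooled == pooled[0]):
        p = 1.0
    else:
        p = float(sps.ranksums(hi, lo).pvalue)
    return MedianSplitResult(
        high_idx=high_idx,
        low_idx=low_idx,
        high_mean=float(hi.mean()),
        low_mean=float(lo.mean()),
        p=p,
    )
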