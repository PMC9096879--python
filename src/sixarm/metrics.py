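"""Descriptive statistics computed from arm-visit trajectories.

Exploratory-period preferences (arm probabilities, neighbor transitions,
directional inertia, two-away transitions), sweep structure, direction
alternation, and within-contingency performance curves with
trials-to-criterion.  Transitions never cross session boundaries: the first
visit of a session starts from the rest box, not from the previous session's
last arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from sixarm.task import REST, Contingency


def smooth_gaussian(x: np.ndarray, sd: float, truncate: float = 4.0) -> np.ndarray:
    """Gaussian smoothing with a truncated kernel renormalized at the edges.

    The kernel extends to ``truncate`` standard deviations; near the series
    edges the overhanging kernel mass is dropped and the remaining weights
    renormalized, so the output is always a convex combination of inputs and
    stays inside their range.  ``sd <= 0`` returns the input unchanged.
    """
    x = np.asarray(x, dtype=float)
    if sd <= 0 or x.size == 0:
        return x.copy()
    radius = max(int(np.ceil(truncate * sd)), 1)
    t = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (t / sd) ** 2)
    # full convolution with an explicit center slice: np.convolve's "same"
    # mode returns the wrong length when the kernel outgrows the series
    num = np.convolve(x, kernel, mode="full")[radius : radius + x.size]
    den = np.convolve(np.ones_like(x), kernel, mode="full")[radius : radius + x.size]
    return num / den


def _as_sessions(visits) -> list[np.ndarray]:
    """Normalize input to a list of per-session arm arrays."""
    if isinstance(visits, pd.DataFrame):
        return [
            g["arm"].to_numpy()
            for _, g in visits.groupby(["rat_id", "phase", "session"], sort=False)
        ]
    visits = list(visits)
    if visits and np.isscalar(visits[0]):
        return [np.asarray(visits)]
    return [np.asarray(v) for v in visits]


@dataclass
class PreferenceStats:
    """Exploratory spatial-preference summary for one animal."""

    arm_probs: np.ndarray  # (6,) visit probabilities, sums to 1
    transition_matrix: np.ndarray  # (6, 6) row-stochastic over visited rows
    max_arm_prob: float
    neighbor_freq: float  # fraction of transitions to +/-1 arms
    inertia: float  # fraction of transitions continuing the previous direction
    two_away_given_not_neighbor: float
    n_visits: int
    n_transitions: int


def preference_stats(visits) -> PreferenceStats:
    """Compute exploratory preference statistics.

    ``visits`` may be a trajectory DataFrame, a flat arm sequence, or a list
    of per-session arm sequences.  Directional inertia is the frequency of
    continuing in the same direction as on the immediately preceding
    transition; the two-away fraction conditions on transitions that do not
    go to a neighboring arm.
    """
    sessions = _as_sessions(visits)
    all_arms = np.concatenate(sessions) if sessions else np.array([])
    if all_arms.size < 2:
        raise ValueError("need at least two visits")

    counts = np.bincount(all_arms.astype(int), minlength=7)[1:7]
    arm_probs = counts / counts.sum()

    trans_counts = np.zeros((6, 6))
    deltas: list[np.ndarray] = []
    inertia_pairs = []
    for arms in sessions:
        arms = arms.astype(int)
        if len(arms) < 2:
            continue
        d = np.diff(arms)
        deltas.append(d)
        np.add.at(trans_counts, (arms[:-1] - 1, arms[1:] - 1), 1)
        if len(d) >= 2:
            inertia_pairs.append(np.sign(d[1:]) == np.sign(d[:-1]))

    row_sums = trans_counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tmat = np.where(row_sums > 0, trans_counts / row_sums, 0.0)

    d_all = np.concatenate(deltas)
    step = np.abs(d_all)
    neighbor_freq = float(np.mean(step == 1))
    not_nb = step != 1
    two_away = float(np.mean(step[not_nb] == 2)) if not_nb.any() else np.nan
    inertia = (
        float(np.concatenate(inertia_pairs).mean()) if inertia_pairs else np.nan
    )

    return PreferenceStats(
        arm_probs=arm_probs,
        transition_matrix=tmat,
        max_arm_prob=float(arm_probs.max()),
        neighbor_freq=neighbor_freq,
        inertia=inertia,
        two_away_given_not_neighbor=two_away,
        n_visits=int(all_arms.size),
        n_transitions=int(d_all.size),
    )


def _sweep_runs(arms: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal monotone runs as (first_visit, last_visit, span_in_arms).

    A direction change starts a new run; the pivot visit belongs to the run
    it terminates.  Span is the number of distinct arms covered,
    ``|end - start| + 1``.
    """
    arms = np.asarray(arms, dtype=int)
    n = len(arms)
    if n < 2:
        return [(0, n - 1, 1)] if n else []
    d = np.diff(arms)
    signs = np.sign(d)
    runs = []
    start = 0  # index of first delta in the run
    for i in range(1, len(d)):
        if signs[i] != signs[start]:
            runs.append((start, i - 1))
            start = i
    runs.append((start, len(d) - 1))
    out = []
    for j, (i0, i1) in enumerate(runs):
        first_visit = i0 if j == 0 else i0 + 1  # pivot stays with the old run
        last_visit = i1 + 1
        span = abs(int(arms[i1 + 1]) - int(arms[i0])) + 1
        out.append((first_visit, last_visit, span))
    return out


def large_sweep_rate(visits, span_threshold: int = 3) -> float:
    """Proportion of arm visits belonging to a sweep spanning > ``span_threshold`` arms.

    A sweep is a maximal monotone run of consecutive visits; sessions are
    segmented independently and the rate pools visits across sessions.
    """
    sessions = _as_sessions(visits)
    total = 0
    counted = 0
    for arms in sessions:
        arms = np.asarray(arms)
        total += len(arms)
        for first, last, span in _sweep_runs(arms):
            if span > span_threshold:
                counted += last - first + 1
    if total == 0:
        raise ValueError("need at least one visit")
    return counted / total


def large_sweep_rate_by_session(visits, span_threshold: int = 3) -> np.ndarray:
    """Per-session large-sweep rates, in session order."""
    return np.array(
        [large_sweep_rate([arms], span_threshold) for arms in _as_sessions(visits)]
    )


@dataclass
class DirectionAlternation:
    """Trial-by-trial direction-alternation structure of a visit sequence."""

    events: np.ndarray  # 0/1 per defined trial: did the continue/reverse label flip?
    smoothed: np.ndarray
    rate: float


def direction_alternation_rate(visits, smooth_sd: float = 10.0) -> DirectionAlternation:
    """Rate at which choices flip between continuing and reversing direction.

    Each trial is labeled *continue* or *reverse* relative to the previous
    transition's direction; an alternation event occurs when the label
    differs from the preceding trial's label.  Labels are computed within
    sessions and the event series pooled across them.
    """
    sessions = _as_sessions(visits)
    events_all = []
    for arms in sessions:
        d = np.diff(np.asarray(arms, dtype=int))
        if len(d) < 3:
            continue
        cont = np.sign(d[1:]) == np.sign(d[:-1])
        events_all.append((cont[1:] != cont[:-1]).astype(float))
    if not events_all:
        raise ValueError("need at least three transitions in some session")
    events = np.concatenate(events_all)
    return DirectionAlternation(
        events=events,
        smoothed=smooth_gaussian(events, smooth_sd),
        rate=float(events.mean()),
    )


@dataclass
class PerformanceCurves:
    """Smoothed within-contingency performance of one animal or model average.

    Error-likelihood curves are computed per trial type in trial-type index,
    then linearly interpolated onto the arm-visit index so all three curves
    share an x axis.  ``trials_to_75`` is the first visit (1-based) at which
    the smoothed reward probability exceeds 0.75, or None.
    """

    reward_prob: np.ndarray  # (n_visits,)
    inbound_err: np.ndarray  # (n_visits,) interpolated
    outbound_err: np.ndarray
    inbound_err_trials: np.ndarray  # raw 0/1 errors in inbound-trial order
    outbound_err_trials: np.ndarray
    inbound_positions: np.ndarray  # visit index (0-based) of each inbound trial
    outbound_positions: np.ndarray
    trials_to_75: int | None


def trial_types(arms: np.ndarray, prev: np.ndarray, center: int) -> np.ndarray:
    """Classify each visit: 1 = outbound, 0 = inbound, -1 = undefined (from rest).

    A visit is outbound iff the trial starts from the contingency's center
    arm; trials starting from any other arm are inbound.
    """
    prev = np.asarray(prev, dtype=int)
    out = np.where(prev == center, 1, 0)
    out = np.where(prev == REST, -1, out)
    return out


def crossing_index(curve: np.ndarray, threshold: float = 0.75) -> int | None:
    """First 1-based index where the curve exceeds the threshold, else None."""
    above = np.nonzero(np.asarray(curve) > threshold)[0]
    return int(above[0]) + 1 if above.size else None


def performance_curves(
    block: pd.DataFrame,
    contingency: Contingency | str | None = None,
    smooth_sd: float = 10.0,
    error_smooth_sd: float = 10.0,
) -> PerformanceCurves:
    """Performance curves for one contingency block of one animal.

    ``block`` is a trajectory table slice covering a single contingency;
    smoothing never crosses the block boundary.  ``smooth_sd`` applies to the
    reward-probability curve (in arm visits) and ``error_smooth_sd`` to the
    per-trial-type error curves (in trials of that type).
    """
    if len(block) == 0:
        raise ValueError("empty contingency block")
    if contingency is None:
        labels = block["contingency_label"].unique()
        if len(labels) != 1:
            raise ValueError(f"block covers several contingencies: {labels}")
        contingency = Contingency.from_label(str(labels[0]))
    elif isinstance(contingency, str):
        contingency = Contingency.from_label(contingency)

    arms = block["arm"].to_numpy(dtype=int)
    rewarded = block["rewarded"].to_numpy(dtype=float)
    sess = block["session"].to_numpy()
    prev = np.empty_like(arms)
    prev[0] = REST
    prev[1:] = np.where(sess[1:] == sess[:-1], arms[:-1], REST)

    ttypes = trial_types(arms, prev, contingency.center)
    errors = 1.0 - rewarded
    n = len(arms)

    reward_prob = smooth_gaussian(rewarded, smooth_sd)

    def type_curve(code: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pos = np.nonzero(ttypes == code)[0]
        raw = errors[pos]
        if pos.size == 0:
            return np.full(n, np.nan), raw, pos
        sm = smooth_gaussian(raw, error_smooth_sd)
        return np.interp(np.arange(n), pos, sm), raw, pos

    inbound_interp, in_raw, in_pos = type_curve(0)
    outbound_interp, out_raw, out_pos = type_curve(1)

    return PerformanceCurves(
        reward_prob=reward_prob,
        inbound_err=inbound_interp,
        outbound_err=outbound_interp,
        inbound_err_trials=in_raw,
        outbound_err_trials=out_raw,
        inbound_positions=in_pos,
        outbound_positions=out_pos,
        trials_to_75=crossing_index(reward_prob),
    )


def contingency_blocks(df: pd.DataFrame) -> list[tuple[str, pd.DataFrame]]:
    """Split one rat's alternation rows into contiguous contingency blocks.

    Returns ``(label, sub-table)`` pairs in temporal order.  Labels may
    repeat across the schedule (a contingency can be revisited), which is
    why blocks are recovered from contiguity rather than from the label.
    """
    alt = df[df["phase"] == "alt"]
    if alt.empty:
        return []
    labels = alt["contingency_label"].astype(str).to_numpy()
    change = np.ones(len(alt), dtype=bool)
    change[1:] = labels[1:] != labels[:-1]
    block_id = np.cumsum(change)
    return [
        (str(g["contingency_label"].iloc[0]), g)
        for _, g in alt.groupby(block_id, sort=False)
    ]
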