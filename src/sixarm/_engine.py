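"""Vectorized episode runner: many seeded agent repeats stepped in lockstep.

Model fitting averages the behavior of hundreds of stochastic repeats per
objective evaluation, so the per-trial agent update must be cheap.  This
module runs all repeats simultaneously with numpy, one array operation per
quantity per trial, and exploits the fact that the forgetting decay
``(1 - omega)`` is applied uniformly to *every* propensity entry on every
trial: instead of multiplying the full propensity tensors each step, each
repeat carries a scalar scale factor and the tensors store rescaled values.
That turns the per-trial cost from O(repeats * 6 * 43) into O(repeats * 6).

Per-repeat random streams come from ``numpy`` generators seeded ``seed + k``
for repeat ``k``; each trial consumes exactly one uniform, so a batch run is
bit-identical to running each repeat alone with its own seed.  Equivalence
with the scalar reference operations in :mod:`sixarm.agents` is asserted in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sixarm.agents import ModelParams, ModelSpec, N_STATES, PropensitySet
from sixarm.task import Schedule

# Internally arms are 0..5 and 6 denotes the rest box; -1 denotes "none".
_REST = 6
_NONE = -1

# State-index lookup: rows = previous location, cols = current location.
_SIDX = np.full((7, 7), -1, dtype=np.int64)
for _p in range(6):
    for _c in range(6):
        _SIDX[_p, _c] = _p * 6 + _c
for _c in range(6):
    _SIDX[_REST, _c] = 36 + _c
_SIDX[_REST, _REST] = 42

# Neighbor masks: _NBMASK[d][cur, a] == 1 iff arm a is cur +/- d, in range.
def _nbmask(distance: int) -> np.ndarray:
    mask = np.zeros((7, 6))
    for cur in range(6):
        for a in (cur - distance, cur + distance):
            if 0 <= a < 6:
                mask[cur, a] = 1.0
    return mask


_NB1 = _nbmask(1)
_NB2 = _nbmask(2)
_AR6 = np.arange(6)

#: Safety valve: an alternation session is cut off after this many visits
#: per required center visit (only reachable in degenerate parameter
#: regions where the policy almost never samples the center arm).
SESSION_CAP_FACTOR = 60


@dataclass
class _FlatSchedule:
    kind: np.ndarray  # (S,) 0 = explore, 1 = alt
    limit: np.ndarray  # (S,) rewards (explore) or center visits (alt)
    low: np.ndarray  # (S,) 0-based contingency arms; -1 for explore
    ctr: np.ndarray
    high: np.ndarray
    phase: np.ndarray  # (S,) phase index within the schedule

    @classmethod
    def from_schedule(cls, schedule: Schedule) -> "_FlatSchedule":
        kind, limit, low, ctr, high, phase = [], [], [], [], [], []
        for pi, ph in enumerate(schedule.phases):
            for lim in ph.session_limits:
                kind.append(0 if ph.kind == "explore" else 1)
                limit.append(lim)
                if ph.contingency is not None:
                    l, c, h = ph.contingency.arms
                    low.append(l - 1)
                    ctr.append(c - 1)
                    high.append(h - 1)
                else:
                    low.append(_NONE)
                    ctr.append(_NONE)
                    high.append(_NONE)
                phase.append(pi)
        return cls(
            kind=np.array(kind, dtype=np.int8),
            limit=np.array(limit, dtype=np.int64),
            low=np.array(low, dtype=np.int64),
            ctr=np.array(ctr, dtype=np.int64),
            high=np.array(high, dtype=np.int64),
            phase=np.array(phase, dtype=np.int64),
        )


@dataclass
class BatchResult:
    """Recorded visits and final propensities of a batch of repeats.

    Per-visit arrays have shape ``(n_repeats, T)`` padded with -1 beyond each
    repeat's length; arms are 1-based (matching the public convention), and
    ``prev`` is the arm the trial started from (0 = rest box).
    """

    spec: ModelSpec
    params: ModelParams
    schedule: Schedule
    seed: int
    arms: np.ndarray  # (R, T) int16, 1..6, -1 pad
    prev: np.ndarray  # (R, T) int16, 0 = REST, 1..6, -1 pad
    rewarded: np.ndarray  # (R, T) int8 0/1, -1 pad
    phase: np.ndarray  # (R, T) int16 phase index, -1 pad
    session: np.ndarray  # (R, T) int32 global session ordinal, -1 pad
    lengths: np.ndarray  # (R,)
    b_trans: np.ndarray  # (R, 6, 43) final propensities
    b_arm: np.ndarray  # (R, 6)
    b_n1: np.ndarray  # (R,)
    b_n2: np.ndarray  # (R,)
    v: np.ndarray  # (R, 43)

    @property
    def n_repeats(self) -> int:
        return self.arms.shape[0]

    def propensities(self, k: int) -> PropensitySet:
        return PropensitySet(
            b_trans=self.b_trans[k].copy(),
            b_arm=self.b_arm[k].copy(),
            b_n1=float(self.b_n1[k]),
            b_n2=float(self.b_n2[k]),
            v=self.v[k].copy(),
        )

    def trajectory(self, k: int, rat_id: str = "model") -> pd.DataFrame:
        """One repeat as a standard trajectory table."""
        n = int(self.lengths[k])
        phase_idx = self.phase[k, :n]
        phases = self.schedule.phases
        kind = np.array(
            ["explore" if phases[i].kind == "explore" else "alt" for i in phase_idx]
        )
        labels = np.array(
            [
                phases[i].contingency.label if phases[i].contingency else ""
                for i in phase_idx
            ]
        )
        sess = self.session[k, :n]
        # trial = visit number within (phase, session), 1-based
        trial = np.ones(n, dtype=int)
        if n:
            new = np.ones(n, dtype=bool)
            new[1:] = (phase_idx[1:] != phase_idx[:-1]) | (sess[1:] != sess[:-1])
            starts = np.nonzero(new)[0]
            counts = np.diff(np.append(starts, n))
            trial = np.arange(n) - np.repeat(starts, counts) + 1
        return pd.DataFrame(
            {
                "rat_id": rat_id,
                "phase": kind,
                "contingency_label": labels,
                "session": sess,
                "trial": trial,
                "arm": self.arms[k, :n],
                "rewarded": self.rewarded[k, :n],
            }
        )

    def trajectories(self, prefix: str = "rep") -> list[pd.DataFrame]:
        return [self.trajectory(k, f"{prefix}{k}") for k in range(self.n_repeats)]

    def phase_reward_matrix(self, phase_index: int) -> np.ndarray:
        """Per-repeat reward indicators for one phase, nan-padded to equal length.

        Rows are repeats; column ``j`` is the reward flag of that repeat's
        ``j``-th visit within the phase (NaN once the repeat's phase is over).
        """
        masks = self.phase == phase_index
        counts = masks.sum(axis=1)
        width = int(counts.max())
        out = np.full((self.n_repeats, width), np.nan)
        for k in range(self.n_repeats):
            vals = self.rewarded[k][masks[k]]
            out[k, : len(vals)] = vals
        return out

    def mean_total_reward(self) -> float:
        """Average over repeats of the total rewards collected."""
        rew = np.where(self.rewarded > 0, 1.0, 0.0)
        return float(rew.sum(axis=1).mean())


def run_batch(
    spec: ModelSpec,
    params: ModelParams,
    schedule: Schedule,
    n_repeats: int,
    seed: int,
    init: PropensitySet | None = None,
) -> BatchResult:
    """Run ``n_repeats`` seeded episodes of the agent over ``schedule``."""
    if n_repeats <= 0:
        raise ValueError("n_repeats must be positive")
    flat = _FlatSchedule.from_schedule(schedule)
    S = len(flat.kind)
    R = n_repeats
    alpha, gamma, omega = params.alpha, params.gamma, params.omega
    decay = 1.0 - omega

    # Plastic quantities, stored rescaled; actual value = scale[k] * stored.
    B = np.zeros((R, 6, N_STATES))
    A = np.zeros((R, 6))
    N1 = np.zeros(R)
    N2 = np.zeros(R)
    V = np.zeros((R, N_STATES))
    scale = np.ones(R)
    if init is not None:
        B[:] = init.b_trans[None]
        A[:] = init.b_arm[None]
        N1[:] = init.b_n1
        N2[:] = init.b_n2
        V[:] = init.v[None]

    prev = np.full(R, _REST, dtype=np.int64)
    cur = np.full(R, _REST, dtype=np.int64)
    last_arm = np.full(R, _REST, dtype=np.int64)
    last_outer = np.full(R, _NONE, dtype=np.int64)
    lobc = np.full(R, _NONE, dtype=np.int64)
    n_center = np.zeros(R, dtype=np.int64)
    n_rew = np.zeros(R, dtype=np.int64)
    n_sess_visits = np.zeros(R, dtype=np.int64)
    sess = np.zeros(R, dtype=np.int64)
    active = np.ones(R, dtype=bool)

    gens = [np.random.default_rng(seed + k) for k in range(R)]
    ublock = np.empty((R, 0))
    ucol = 0
    UCHUNK = 512

    est = int(flat.limit.sum() * 4 + 64)
    cap = est
    arms_rec = np.full((R, cap), -1, dtype=np.int16)
    prev_rec = np.full((R, cap), -1, dtype=np.int16)
    rew_rec = np.full((R, cap), -1, dtype=np.int8)
    phase_rec = np.full((R, cap), -1, dtype=np.int16)
    sess_rec = np.full((R, cap), -1, dtype=np.int32)

    t = 0
    while True:
        act = np.nonzero(active)[0]
        if act.size == 0:
            break
        if t >= cap:
            grow = max(cap // 2, 256)
            pad = lambda a, fill, dt: np.concatenate(
                [a, np.full((R, grow), fill, dtype=dt)], axis=1
            )
            arms_rec = pad(arms_rec, -1, np.int16)
            prev_rec = pad(prev_rec, -1, np.int16)
            rew_rec = pad(rew_rec, -1, np.int8)
            phase_rec = pad(phase_rec, -1, np.int16)
            sess_rec = pad(sess_rec, -1, np.int32)
            cap += grow

        p_arm = prev[act]
        c_arm = cur[act]
        s = _SIDX[p_arm, c_arm]
        sc = scale[act]

        m = B[act[:, None], _AR6[None, :], s[:, None]] * sc[:, None]
        if spec.include_arm:
            m += A[act] * sc[:, None]
        if spec.include_neighbor:
            m += (N1[act] * sc)[:, None] * _NB1[c_arm]
            m += (N2[act] * sc)[:, None] * _NB2[c_arm]

        on_track = c_arm < 6
        rows = np.nonzero(on_track)[0]
        m[rows, c_arm[rows]] = -np.inf
        m -= m.max(axis=1, keepdims=True)
        np.exp(m, out=m)
        p = m / m.sum(axis=1, keepdims=True)

        if ucol >= ublock.shape[1]:
            ublock = np.stack([g.random(UCHUNK) for g in gens])
            ucol = 0
        u = ublock[act, ucol]
        ucol += 1
        cum = np.cumsum(p, axis=1)
        cum[:, -1] = 1.0  # absorb float rounding in the last CDF bucket
        choice = (cum > u[:, None]).argmax(axis=1)
        bad = choice == c_arm
        if np.any(bad):  # float rounding at the top of the CDF
            masked = np.where(p > 0, p, -1.0)
            choice[bad] = masked[bad].argmax(axis=1)

        # --- environment ---------------------------------------------------
        k_s = flat.kind[sess[act]]
        is_alt = k_s == 1
        low_s = flat.low[sess[act]]
        ctr_s = flat.ctr[sess[act]]
        high_s = flat.high[sess[act]]
        la = last_arm[act]

        is_center = is_alt & (choice == ctr_s)
        is_outer = is_alt & ((choice == low_s) | (choice == high_s))
        rew_alt = (is_center & (la != ctr_s)) | (
            is_outer & (la == ctr_s) & (lobc[act] != choice)
        )
        rew = np.where(is_alt, rew_alt, choice != la).astype(np.int8)

        lobc[act] = np.where(is_center, last_outer[act], lobc[act])
        last_outer[act] = np.where(is_outer, choice, last_outer[act])
        last_arm[act] = choice
        n_center[act] += is_center
        n_rew[act] += rew
        n_sess_visits[act] += 1

        # --- learning ------------------------------------------------------
        s2 = _SIDX[c_arm, choice]
        v_t = V[act, s] * sc
        v_t1 = V[act, s2] * sc
        delta = rew + gamma * v_t1 - v_t

        scale[act] = sc = sc * decay
        coef = alpha * delta / sc
        inc = -coef[:, None] * p
        inc[np.arange(act.size), choice] += coef
        B[act[:, None], _AR6[None, :], s[:, None]] += inc
        if spec.include_arm:
            A[act] += inc
        if spec.include_neighbor:
            p1 = (p * _NB1[c_arm]).sum(axis=1)
            p2 = (p * _NB2[c_arm]).sum(axis=1)
            N1[act] += coef * (_NB1[c_arm, choice] - p1)
            N2[act] += coef * (_NB2[c_arm, choice] - p2)
        V[act, s] += coef

        if np.any(sc < 1e-120):  # refresh the scale factor before underflow
            small = act[sc < 1e-120]
            B[small] *= scale[small, None, None]
            A[small] *= scale[small, None]
            N1[small] *= scale[small]
            N2[small] *= scale[small]
            V[small] *= scale[small, None]
            scale[small] = 1.0

        # --- recording -----------------------------------------------------
        arms_rec[act, t] = choice + 1
        prev_rec[act, t] = np.where(c_arm == _REST, 0, c_arm + 1)
        rew_rec[act, t] = rew
        phase_rec[act, t] = flat.phase[sess[act]]
        sess_rec[act, t] = sess[act]

        # --- session bookkeeping -------------------------------------------
        lim = flat.limit[sess[act]]
        capped = is_alt & (n_sess_visits[act] >= SESSION_CAP_FACTOR * lim + 60)
        end_alt = is_alt & (((n_center[act] >= lim) & (choice != ctr_s)) | capped)
        end_exp = (~is_alt) & (n_rew[act] >= lim)
        ended = end_alt | end_exp

        prev[act] = c_arm
        cur[act] = choice

        if np.any(ended):
            e = act[ended]
            sess[e] += 1
            prev[e] = _REST
            cur[e] = _REST
            last_arm[e] = _REST
            last_outer[e] = _NONE
            lobc[e] = _NONE
            n_center[e] = 0
            n_rew[e] = 0
            n_sess_visits[e] = 0
            finished = e[sess[e] >= S]
            active[finished] = False
        t += 1

    lengths = (arms_rec >= 0).sum(axis=1)
    T = int(lengths.max()) if R else 0
    return BatchResult(
        spec=spec,
        params=params,
        schedule=schedule,
        seed=seed,
        arms=arms_rec[:, :T],
        prev=prev_rec[:, :T],
        rewarded=rew_rec[:, :T],
        phase=phase_rec[:, :T],
        session=sess_rec[:, :T],
        lengths=lengths,
        b_trans=B * scale[:, None, None],
        b_arm=A * scale[:, None],
        b_n1=N1 * scale,
        b_n2=N2 * scale,
        v=V * scale[:, None],
    )
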