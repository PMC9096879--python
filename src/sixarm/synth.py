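"""Synthetic rat cohorts with known ground truth.

Exploration is generated by a kernel that mirrors the preferences real
animals show before ever encountering the alternation rule: static arm
preferences, a bias toward neighboring arms, and directional inertia.
Alternation behavior is then produced by an M3 agent whose propensities were
initialized by forcing it through that same exploration — exactly the
procedure used when fitting real animals — so every synthetic rat has a
known (alpha, gamma, omega) ground truth for recovery experiments.

Default cohort scale mimics the study conditions: 24 rats, 15 exploration
sessions of 25 rewards each (375 exploratory trials, within the observed
362-425 range), and six alternation contingencies in the order
234, 123, 345, 246, 234, 456.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sixarm.agents import ModelParams, ModelSpec, force_trajectory
from sixarm._engine import run_batch
from sixarm.task import REST, Schedule, reward_exploration


@dataclass
class SyntheticRatConfig:
    """Generative settings for one synthetic rat.

    arm_pref_weights : relative visit propensities per arm (non-negative,
        not all zero); the sampling kernel multiplies these in
    neighbor_bias : log-propensity added to transitions to arms +/-1 away
    inertia_bias : log-propensity added to transitions continuing the
        previous direction of travel (dropped at the track edges, where no
        continuing move exists)
    m3_params : ground-truth agent parameters for the alternation phase
        (None = exploration only)
    """

    arm_pref_weights: np.ndarray
    neighbor_bias: float = 0.0
    inertia_bias: float = 0.0
    explore_sessions: int = 15
    rewards_per_explore_session: int = 25
    m3_params: ModelParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.arm_pref_weights = np.asarray(self.arm_pref_weights, dtype=float)
        if self.arm_pref_weights.shape != (6,):
            raise ValueError("arm_pref_weights must be a 6-vector")
        if np.any(self.arm_pref_weights < 0) or not np.any(self.arm_pref_weights > 0):
            raise ValueError("weights must be non-negative and not all zero")
        if self.neighbor_bias < 0 or self.inertia_bias < 0:
            raise ValueError("biases must be non-negative")

    def to_dict(self) -> dict:
        return {
            "arm_pref_weights": self.arm_pref_weights.tolist(),
            "neighbor_bias": self.neighbor_bias,
            "inertia_bias": self.inertia_bias,
            "explore_sessions": self.explore_sessions,
            "rewards_per_explore_session": self.rewards_per_explore_session,
            "m3_params": self.m3_params.as_dict() if self.m3_params else None,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticRatConfig":
        p = d.get("m3_params")
        return cls(
            arm_pref_weights=np.asarray(d["arm_pref_weights"], dtype=float),
            neighbor_bias=float(d["neighbor_bias"]),
            inertia_bias=float(d["inertia_bias"]),
            explore_sessions=int(d["explore_sessions"]),
            rewards_per_explore_session=int(d["rewards_per_explore_session"]),
            m3_params=ModelParams(**p) if p else None,
            seed=int(d["seed"]),
        )


def explore_session_arms(
    cfg: SyntheticRatConfig, rng: np.random.Generator, n_visits: int
) -> np.ndarray:
    """Sample one exploration session of ``n_visits`` arms from the kernel.

    The probability of moving to arm ``a`` from current arm ``c`` (previous
    direction ``d``) is proportional to
    ``w_a * exp(neighbor_bias * [|a-c|=1] + inertia_bias * [sign(a-c)=d])``
    with the current arm excluded; from the rest box it is proportional to
    the weights alone.
    """
    arms = np.empty(n_visits, dtype=int)
    w = cfg.arm_pref_weights
    targets = np.arange(1, 7)
    cur = REST
    direction = 0
    for i in range(n_visits):
        logit = np.log(np.where(w > 0, w, 1e-300))
        if cur != REST:
            dist = np.abs(targets - cur)
            logit = logit + cfg.neighbor_bias * (dist == 1)
            if direction != 0:
                logit = logit + cfg.inertia_bias * (np.sign(targets - cur) == direction)
            logit[cur - 1] = -np.inf
            logit[w == 0] = -np.inf
        else:
            logit[w == 0] = -np.inf
        p = np.exp(logit - logit.max())
        p /= p.sum()
        arm = int(rng.choice(targets, p=p))
        if cur != REST:
            direction = int(np.sign(arm - cur))
        cur = arm
        arms[i] = arm
    return arms


def gen_exploration(cfg: SyntheticRatConfig, rat_id: str = "rat") -> pd.DataFrame:
    """Generate the full exploratory phase of one rat as a trajectory table.

    In the generated behavior (no immediate revisits) every visit is
    rewarded, so a session of ``rewards_per_explore_session`` rewards has
    exactly that many visits.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for s in range(cfg.explore_sessions):
        arms = explore_session_arms(cfg, rng, cfg.rewards_per_explore_session)
        prev = REST
        for t, arm in enumerate(arms, start=1):
            rows.append(
                {
                    "rat_id": rat_id,
                    "phase": "explore",
                    "contingency_label": "",
                    "session": s,
                    "trial": t,
                    "arm": int(arm),
                    "rewarded": int(reward_exploration(prev, int(arm))),
                }
            )
            prev = int(arm)
    return pd.DataFrame(rows)


@dataclass
class CohortManifest:
    """A full synthetic cohort: per-rat generative configs plus the schedule."""

    rats: dict[str, SyntheticRatConfig]
    schedule: Schedule

    def to_dict(self) -> dict:
        return {
            "rats": {rid: cfg.to_dict() for rid, cfg in self.rats.items()},
            "schedule": self.schedule.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortManifest":
        return cls(
            rats={
                rid: SyntheticRatConfig.from_dict(c) for rid, c in d["rats"].items()
            },
            schedule=Schedule.from_dict(d["schedule"]),
        )

    @classmethod
    def default_cohort(
        cls,
        n_rats: int = 24,
        seed: int = 0,
        schedule: Schedule | None = None,
        explore_sessions: int = 15,
        rewards_per_explore_session: int = 25,
    ) -> "CohortManifest":
        """Draw a heterogeneous cohort with in-bounds ground-truth parameters.

        Arm-preference weights come from a Dirichlet prior, neighbor and
        inertia biases span the range from weak to strong preference, and
        (alpha, gamma, omega) are drawn uniformly over the interior of the
        fitting bounds.
        """
        rng = np.random.default_rng(seed)
        schedule = schedule or Schedule.default(
            explore_sessions=explore_sessions,
            rewards_per_explore_session=rewards_per_explore_session,
        )
        rats = {}
        for i in range(n_rats):
            params = ModelParams(
                alpha=float(rng.uniform(0.1, 0.9)),
                gamma=float(rng.uniform(0.1, 0.9)),
                omega=float(rng.uniform(0.001, 0.015)),
            )
            rats[f"rat{i:02d}"] = SyntheticRatConfig(
                arm_pref_weights=rng.dirichlet(np.full(6, 4.0)),
                neighbor_bias=float(rng.uniform(0.3, 2.0)),
                inertia_bias=float(rng.uniform(0.1, 1.5)),
                explore_sessions=explore_sessions,
                rewards_per_explore_session=rewards_per_explore_session,
                m3_params=params,
                seed=int(seed + 1000 + 17 * i),
            )
        return cls(rats=rats, schedule=schedule)


def gen_rat(
    cfg: SyntheticRatConfig, schedule: Schedule, rat_id: str = "rat"
) -> pd.DataFrame:
    """One rat: kernel-generated exploration, then M3 alternation play.

    The agent is forced through the rat's own exploration (initializing its
    propensities), then plays the schedule's alternation phases as a single
    stochastic realization.
    """
    df = gen_exploration(cfg, rat_id)
    if cfg.m3_params is None:
        return df
    sessions = [
        g["arm"].to_numpy(dtype=int) for _, g in df.groupby("session", sort=True)
    ]
    init = force_trajectory("M3", cfg.m3_params, sessions)
    alt_phases = [p for p in schedule.phases if p.kind == "alt"]
    if not alt_phases:
        return df
    alt_sched = Schedule(tuple(alt_phases))
    res = run_batch(
        ModelSpec.from_name("M3"),
        cfg.m3_params,
        alt_sched,
        n_repeats=1,
        seed=cfg.seed + 500_000,
        init=init,
    )
    alt_df = res.trajectory(0, rat_id)
    alt_df["session"] = alt_df["session"] + cfg.explore_sessions
    return pd.concat([df, alt_df], ignore_index=True)


def gen_cohort(manifest: CohortManifest) -> tuple[pd.DataFrame, dict]:
    """Generate the cohort trajectory table and its ground-truth record."""
    frames = [
        gen_rat(cfg, manifest.schedule, rat_id) for rat_id, cfg in manifest.rats.items()
    ]
    truth = {
        "rats": {rid: cfg.to_dict() for rid, cfg in manifest.rats.items()},
        "schedule": manifest.schedule.to_dict(),
    }
    return pd.concat(frames, ignore_index=True), truth
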