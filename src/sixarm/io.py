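"""Trajectory file formats, run configuration, and the analysis pipeline.

The canonical trajectory format is a CSV with header
``rat_id,phase,contingency_label,session,trial,arm,rewarded``: one row per
arm visit, arms 1-based, ``phase`` either ``explore`` or ``alt``,
``session`` a global per-rat session ordinal and ``trial`` the 1-based visit
number within the session.  Because a contingency can recur in the schedule,
contingency blocks are identified by contiguity, not by label.

:func:`run_pipeline` strings the package together in the analysis order used
throughout: exploratory preference statistics and population randomness
tests, reward-maximized model learning curves, per-animal fits on the second
and third contingencies, prediction of the held-out contingencies
(rank-order variance explained, median split), and the sweep /
direction-alternation analyses.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sixarm.agents import ModelParams, ModelSpec
from sixarm._engine import run_batch
from sixarm.agents import force_trajectory
from sixarm.fitting import (
    AnimalFitData,
    AnnealConfig,
    fit_animal,
    group_crossing,
    reward_maximizing_params,
)
from sixarm.metrics import (
    contingency_blocks,
    direction_alternation_rate,
    large_sweep_rate,
    preference_stats,
)
from sixarm.stats import (
    RandomnessEvidence,
    mc_null_p,
    median_split_compare,
    null_inertia,
    null_max_arm_prob,
    null_neighbor_freq,
    population_randomness_test,
    rank_order_r2,
)
from sixarm.task import Schedule

log = logging.getLogger("sixarm")

TRAJECTORY_COLUMNS = [
    "rat_id",
    "phase",
    "contingency_label",
    "session",
    "trial",
    "arm",
    "rewarded",
]


class TrajectoryFormatError(ValueError):
    """A trajectory file violates the documented format."""


def write_trajectories(df: pd.DataFrame, path) -> None:
    """Write a trajectory table in the canonical CSV dialect."""
    out = df[TRAJECTORY_COLUMNS].copy()
    out.to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    """Read and validate a trajectory CSV.

    Raises :class:`TrajectoryFormatError` naming the offending row (1-based,
    counting the header as row 1) for bad arm ids, phases, reward flags, or
    non-monotone trial indices.  Rows are returned ordered by
    (rat, session, trial).
    """
    df = pd.read_csv(path, dtype={"contingency_label": str})
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"missing columns: {missing}")
    extra = [c for c in df.columns if c not in TRAJECTORY_COLUMNS]
    if extra:
        raise TrajectoryFormatError(f"unknown columns: {extra}")
    if df.empty:
        return df
    df["contingency_label"] = df["contingency_label"].fillna("")

    def offending(mask: np.ndarray) -> int:
        return int(np.nonzero(mask)[0][0]) + 2  # +1 header, +1 one-based

    arm = df["arm"].to_numpy()
    bad = ~np.isin(arm, np.arange(1, 7))
    if bad.any():
        raise TrajectoryFormatError(f"bad arm id at line {offending(bad)}")
    rew = df["rewarded"].to_numpy()
    bad = ~np.isin(rew, [0, 1])
    if bad.any():
        raise TrajectoryFormatError(f"bad reward flag at line {offending(bad)}")
    bad = ~df["phase"].isin(["explore", "alt"]).to_numpy()
    if bad.any():
        raise TrajectoryFormatError(f"unknown phase at line {offending(bad)}")
    bad = (df["phase"] == "alt").to_numpy() & (
        df["contingency_label"].str.len() != 3
    ).to_numpy()
    if bad.any():
        raise TrajectoryFormatError(
            f"alternation row without contingency at line {offending(bad)}"
        )
    for (rat, sess), g in df.groupby(["rat_id", "session"], sort=False):
        t = g["trial"].to_numpy()
        if np.any(np.diff(t) <= 0):
            row = g.index[int(np.nonzero(np.diff(t) <= 0)[0][0]) + 1]
            raise TrajectoryFormatError(
                f"non-monotone trial index at line {int(row) + 2} "
                f"(rat {rat!r}, session {sess})"
            )
    return df.sort_values(["rat_id", "session", "trial"], kind="stable").reset_index(
        drop=True
    )


def save_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a pipeline run needs, with seeds explicit.

    Defaults are scaled for a quick desk run (a small cohort, reduced
    repeats); raise ``n_rats``, ``fit_repeats`` and ``rm_repeats`` toward
    study scale (24 rats, 200 repeats) for full-fidelity runs.
    """

    seed: int = 0
    n_rats: int = 6
    schedule: Schedule = field(default_factory=Schedule.default)
    models: tuple[str, ...] = ("M1", "M2", "M3")
    fit_model: str = "M3"
    fitted_contingencies: tuple[int, ...] = (2, 3)
    fit_repeats: int = 50
    fit_restarts: int = 4
    anneal: AnnealConfig = field(default_factory=lambda: AnnealConfig(steps=60))
    rm_repeats: int = 30
    rm_grid_size: int = 4
    curve_repeats: int = 100
    n_null_draws: int = 10_000
    n_perms: int = 10_000
    input_csv: str | None = None  # None = generate a synthetic cohort

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "seed",
                "n_rats",
                "models",
                "fit_model",
                "fitted_contingencies",
                "fit_repeats",
                "fit_restarts",
                "rm_repeats",
                "rm_grid_size",
                "curve_repeats",
                "n_null_draws",
                "n_perms",
                "input_csv",
            )
        }
        d["models"] = list(d["models"])
        d["fitted_contingencies"] = list(d["fitted_contingencies"])
        d["anneal"] = self.anneal.as_dict()
        d["schedule"] = self.schedule.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "schedule" in d:
            d["schedule"] = Schedule.from_dict(d["schedule"])
        if "anneal" in d:
            d["anneal"] = AnnealConfig(**d["anneal"])
        for k in ("models", "fitted_contingencies"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _reward_rate(block_df: pd.DataFrame) -> float:
    return float(block_df["rewarded"].mean())


def _rat_block_rates(df: pd.DataFrame) -> dict[str, list[float]]:
    """Per-rat reward rate in each contingency block, in block order."""
    out = {}
    for rat, g in df.groupby("rat_id", sort=True):
        out[rat] = [_reward_rate(b) for _, b in contingency_blocks(g)]
    return out


def _explore_sessions(df: pd.DataFrame, rat: str) -> list[np.ndarray]:
    g = df[(df["rat_id"] == rat) & (df["phase"] == "explore")]
    return [s["arm"].to_numpy(dtype=int) for _, s in g.groupby("session", sort=True)]


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Run the full analysis sequence on a cohort; return (and write) results.

    Stages: cohort input (or synthesis) → exploratory preference statistics
    with per-animal Monte-Carlo nulls and population randomness tests →
    reward-maximized learning curves per model with 75%-crossing trials →
    per-animal fits on the configured contingencies → prediction of held-out
    contingencies (rank-order r², median split) → large-sweep and
    direction-alternation summaries.
    """
    from sixarm.synth import CohortManifest, gen_cohort

    t_start = time.time()
    results: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        log.info("stage %s", name)
        results["stages"][name] = round(time.time() - t_start, 2)

    # --- data ---------------------------------------------------------------
    stage("data")
    if config.input_csv:
        df = read_trajectories(config.input_csv)
        truth = None
    else:
        manifest = CohortManifest.default_cohort(
            n_rats=config.n_rats, seed=config.seed, schedule=config.schedule
        )
        df, truth = gen_cohort(manifest)
        results["ground_truth"] = truth
    rats = sorted(df["rat_id"].unique())

    # --- exploratory preferences --------------------------------------------
    stage("preferences")
    pref_rows = {}
    phis = {"max_arm_prob": [], "neighbor_freq": [], "inertia": []}
    for i, rat in enumerate(rats):
        sessions = _explore_sessions(df, rat)
        st = preference_stats(sessions)
        pref_rows[rat] = {
            "max_arm_prob": st.max_arm_prob,
            "neighbor_freq": st.neighbor_freq,
            "inertia": st.inertia,
            "two_away_given_not_neighbor": st.two_away_given_not_neighbor,
        }
        base = config.seed + 37 * i
        phis["max_arm_prob"].append(
            mc_null_p(st.max_arm_prob, null_max_arm_prob(sessions),
                      config.n_null_draws, seed=base + 1)
        )
        phis["neighbor_freq"].append(
            mc_null_p(st.neighbor_freq, null_neighbor_freq(sessions),
                      config.n_null_draws, seed=base + 2)
        )
        phis["inertia"].append(
            mc_null_p(st.inertia, null_inertia(sessions),
                      config.n_null_draws, seed=base + 3)
        )
    population_p = {
        stat: population_randomness_test(
            RandomnessEvidence(np.array(vals), stat_name=stat),
            seed=config.seed + 11,
        )
        for stat, vals in phis.items()
    }
    results["preferences"] = {"per_rat": pref_rows, "phi": phis,
                              "population_p": population_p}

    # --- reward-maximized models --------------------------------------------
    stage("reward_max")
    alt_sched = Schedule(tuple(p for p in config.schedule.phases if p.kind == "alt"))
    rm = {}
    for name in config.models:
        params, value = reward_maximizing_params(
            name, alt_sched, n_repeats=config.rm_repeats, seed=config.seed,
            grid_size=config.rm_grid_size,
        )
        res = run_batch(ModelSpec.from_name(name), params, alt_sched,
                        n_repeats=config.curve_repeats, seed=config.seed)
        crossings = [group_crossing(res, pi) for pi in range(len(alt_sched.phases))]
        rm[name] = {
            "params": params.as_dict(),
            "mean_total_reward": value,
            "trials_to_75": crossings,
        }
    results["reward_max"] = rm

    # --- per-animal fits ----------------------------------------------------
    stage("fits")
    fits = {}
    model_rate_fit = []
    model_rate_all = []
    for i, rat in enumerate(rats):
        rat_df = df[df["rat_id"] == rat]
        animal = AnimalFitData.from_frame(rat_df)
        fr = fit_animal(
            animal,
            config.fit_model,
            config.schedule,
            n_restarts=config.fit_restarts,
            n_repeats=config.fit_repeats,
            anneal=config.anneal,
            seed=config.seed + 101 * i,
            fitted_contingencies=config.fitted_contingencies,
        )
        fits[rat] = fr.as_dict()
        # model reward rates with the fitted parameters
        init = force_trajectory(config.fit_model, fr.params, animal.exploration_sessions)
        res = run_batch(
            ModelSpec.from_name(config.fit_model), fr.params, alt_sched,
            n_repeats=config.fit_repeats, seed=config.seed + 101 * i, init=init,
        )
        rew = np.where(res.rewarded >= 0, res.rewarded, 0).astype(float)
        valid = res.rewarded >= 0
        fit_phases = [c - 1 for c in config.fitted_contingencies]
        in_fit = np.isin(res.phase, fit_phases)
        model_rate_fit.append(float(rew[in_fit & valid].sum() / valid[in_fit].sum()))
        model_rate_all.append(float(rew[valid].sum() / valid.sum()))
    results["fits"] = fits

    # --- prediction of held-out contingencies -------------------------------
    stage("prediction")
    block_rates = _rat_block_rates(df)
    n_blocks = len(next(iter(block_rates.values())))
    fit_idx = [c - 1 for c in config.fitted_contingencies]
    unfit_idx = [i for i in range(n_blocks) if i not in fit_idx]
    animal_fit = np.array([np.mean([block_rates[r][i] for i in fit_idx]) for r in rats])
    animal_unfit = np.array(
        [np.mean([block_rates[r][i] for i in unfit_idx]) for r in rats]
    )
    model_fit_arr = np.array(model_rate_fit)
    pred = {
        "r2_fit": rank_order_r2(model_fit_arr, animal_fit),
        "r2_unfit": rank_order_r2(model_fit_arr, animal_unfit),
        "r2_animal_self": rank_order_r2(animal_fit, animal_unfit),
    }
    if len(rats) >= 4:
        split = median_split_compare(model_fit_arr, animal_unfit)
        pred["median_split"] = {
            "high_mean": split.high_mean,
            "low_mean": split.low_mean,
            "p": split.p,
        }
    results["prediction"] = pred

    # --- sweeps and direction alternation -----------------------------------
    stage("sweeps")
    sweep = {}
    for rat in rats:
        rat_df = df[df["rat_id"] == rat]
        expl = rat_df[rat_df["phase"] == "explore"]
        blocks = contingency_blocks(rat_df)
        row = {"explore": large_sweep_rate(expl)}
        if blocks:
            row["contingency1"] = large_sweep_rate(blocks[0][1])
            alt_df = rat_df[rat_df["phase"] == "alt"]
            row["direction_alternation"] = direction_alternation_rate(alt_df).rate
        sweep[rat] = row
    results["sweeps"] = sweep
    if len(rats) >= 3:
        c1 = np.array([sweep[r].get("contingency1", np.nan) for r in rats])
        overall = np.array([np.mean(block_rates[r]) for r in rats])
        if np.all(np.isfinite(c1)):
            r = np.corrcoef(c1, overall)[0, 1]
            results["sweeps_vs_reward_r2"] = float(r**2)

    results["wall_time_s"] = round(time.time() - t_start, 2)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_trajectories(df, out_dir / "trajectories.csv")
        save_json(results, out_dir / "results.json")
    return results
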