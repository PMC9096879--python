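"""Fitting agents to individual animals by approximate Bayesian computation.

The likelihood of an on-policy learning agent is intractable, so parameters
are chosen to make summary statistics of simulated behavior match the
animal's: the agent is first forced through the animal's own exploratory arm
visits (setting its initial propensities), then plays the alternation
schedule freely; the average inbound and outbound error-likelihood curves of
many repeats are compared with the animal's curves by root-mean-square
difference, summed over the two trial types with equal weight.  Every
objective evaluation reuses the same simulation seed, so the objective is a
deterministic function of the parameters and optimization noise comes only
from the optimizer.

Optimization is simulated annealing with several restarts from random
in-bounds initial conditions; the restart with the smallest error wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from sixarm._engine import BatchResult, run_batch
from sixarm.agents import (
    PARAM_BOUNDS,
    ModelParams,
    ModelSpec,
    force_trajectory,
)
from sixarm.metrics import crossing_index, smooth_gaussian, trial_types
from sixarm.task import REST, Schedule


@dataclass(frozen=True)
class AnnealConfig:
    """Simulated-annealing schedule: geometric cooling with Gaussian proposals
    (per-parameter width a fixed fraction of the bound range, reflected at
    the bounds)."""

    t0: float = 1.0
    cooling: float = 0.95
    steps: int = 400
    proposal_frac: float = 0.1

    def as_dict(self) -> dict:
        return {
            "t0": self.t0,
            "cooling": self.cooling,
            "steps": self.steps,
            "proposal_frac": self.proposal_frac,
        }


@dataclass
class FitResult:
    """Outcome of fitting one animal: best parameters and provenance."""

    params: ModelParams
    rms: float
    restart_errors: list[tuple[ModelParams, float]]
    seed: int
    fitted_contingencies: tuple[int, ...]
    n_repeats: int
    anneal: AnnealConfig

    def as_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "rms": self.rms,
            "restarts": [
                {"params": p.as_dict(), "rms": r} for p, r in self.restart_errors
            ],
            "seed": self.seed,
            "fitted_contingencies": list(self.fitted_contingencies),
            "n_repeats": self.n_repeats,
            "anneal": self.anneal.as_dict(),
        }


@dataclass
class AnimalFitData:
    """Everything the objective needs about one animal.

    exploration_sessions : per-session arm sequences of the exploratory phase
    inbound, outbound : per-contingency-block raw 0/1 error series
        (index 0 = first alternation contingency)
    """

    exploration_sessions: list[np.ndarray]
    inbound: list[np.ndarray]
    outbound: list[np.ndarray]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnimalFitData":
        """Build from one rat's trajectory table."""
        from sixarm.metrics import contingency_blocks

        expl = df[df["phase"] == "explore"]
        sessions = [
            g["arm"].to_numpy(dtype=int)
            for _, g in expl.groupby("session", sort=True)
        ]
        inbound, outbound = [], []
        for label, block in contingency_blocks(df):
            from sixarm.task import Contingency

            center = Contingency.from_label(label).center
            arms = block["arm"].to_numpy(dtype=int)
            sess = block["session"].to_numpy()
            prev = np.empty_like(arms)
            prev[0] = REST
            prev[1:] = np.where(sess[1:] == sess[:-1], arms[:-1], REST)
            tt = trial_types(arms, prev, center)
            err = 1.0 - block["rewarded"].to_numpy(dtype=float)
            inbound.append(err[tt == 0])
            outbound.append(err[tt == 1])
        return cls(exploration_sessions=sessions, inbound=inbound, outbound=outbound)


def _pad_to(series: np.ndarray, n: int, fill: float = 0.5) -> np.ndarray:
    """Truncate or edge-pad a series to length n (empty series pad with 0.5)."""
    out = np.full(n, fill if series.size == 0 else float(series[-1]))
    m = min(series.size, n)
    out[:m] = series[:m]
    return out


def model_error_series(
    res: BatchResult, phase_idx: int, center: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-repeat (inbound, outbound) 0/1 error series for one phase."""
    out = []
    in_phase = res.phase == phase_idx
    for k in range(res.n_repeats):
        mask = in_phase[k]
        arms = res.arms[k][mask]
        prev = res.prev[k][mask]
        err = 1.0 - res.rewarded[k][mask]
        tt = trial_types(arms, prev, center)
        out.append((err[tt == 0], err[tt == 1]))
    return out


def reward_curves(res: BatchResult, phase_idx: int, n_trials: int) -> np.ndarray:
    """Per-repeat reward-indicator curves for a phase, aligned to n_trials."""
    mat = np.empty((res.n_repeats, n_trials))
    in_phase = res.phase == phase_idx
    for k in range(res.n_repeats):
        vals = res.rewarded[k][in_phase[k]].astype(float)
        mat[k] = _pad_to(vals, n_trials)
    return mat


def curve_rms(model_curve: np.ndarray, animal_curve: np.ndarray, smooth_sd: float) -> float:
    """RMS difference between two error series after identical smoothing.

    Both inputs are smoothed with the same Gaussian (SD in trials of the
    series' own type) before comparison; a constant offset ``d`` between the
    curves therefore yields exactly ``d``.
    """
    m = smooth_gaussian(np.asarray(model_curve, float), smooth_sd)
    a = smooth_gaussian(np.asarray(animal_curve, float), smooth_sd)
    if m.shape != a.shape:
        raise ValueError("curves must have equal length")
    return float(np.sqrt(np.mean((m - a) ** 2)))


def _alternation_schedule(schedule: Schedule, n_blocks: int) -> Schedule:
    """The first n_blocks alternation phases of a schedule, exploration dropped."""
    alt = schedule.alternation_phases
    if len(alt) < n_blocks:
        raise ValueError(
            f"schedule has {len(alt)} alternation phases, need {n_blocks}"
        )
    return Schedule(tuple(alt[:n_blocks]))


def abc_objective(
    animal: AnimalFitData,
    spec: ModelSpec | str,
    params: ModelParams,
    schedule: Schedule,
    n_repeats: int = 200,
    seed: int = 0,
    fitted_contingencies: Sequence[int] = (2, 3),
    smooth_sd: float = 2.25,
) -> float:
    """RMS mismatch between model-average and animal error curves.

    ``fitted_contingencies`` are 1-based alternation-block numbers.  The
    agent is forced through the animal's exploration, then plays the
    alternation blocks up to the last fitted one.  For each fitted block the
    model's repeats are aligned to the animal's inbound/outbound trial
    counts, averaged, smoothed (Gaussian SD ``smooth_sd`` in trials of each
    type, as for the animal), and compared by RMS; the two trial types are
    summed with equal weight.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    if not params.in_bounds():
        raise ValueError(f"params out of fitting bounds: {params}")
    blocks = sorted(fitted_contingencies)
    if blocks[0] < 1:
        raise ValueError("contingency numbers are 1-based")
    run_sched = _alternation_schedule(schedule, blocks[-1])
    init = force_trajectory(spec, params, animal.exploration_sessions)
    res = run_batch(spec, params, run_sched, n_repeats=n_repeats, seed=seed, init=init)

    rms_in = []
    rms_out = []
    for c in blocks:
        phase_idx = c - 1
        center = run_sched.phases[phase_idx].contingency.center
        series = model_error_series(res, phase_idx, center)
        for animal_raw, which, acc in (
            (animal.inbound[c - 1], 0, rms_in),
            (animal.outbound[c - 1], 1, rms_out),
        ):
            n = len(animal_raw)
            if n == 0:
                continue
            mat = np.vstack([_pad_to(s[which], n) for s in series])
            acc.append(curve_rms(mat.mean(axis=0), animal_raw, smooth_sd))
    if not rms_in and not rms_out:
        raise ValueError("animal has no trials in the fitted contingencies")
    total = 0.0
    if rms_in:
        total += float(np.mean(rms_in))
    if rms_out:
        total += float(np.mean(rms_out))
    return total


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------

def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    # fold the real line onto [lo, hi]
    y = (x - lo) % (2 * span)
    return lo + (y if y <= span else 2 * span - y)


def simulated_annealing(
    objective: Callable[[dict[str, float]], float],
    bounds: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    config: AnnealConfig = AnnealConfig(),
    x0: dict[str, float] | None = None,
) -> tuple[dict[str, float], float, list[float]]:
    """Minimize ``objective`` over a box by simulated annealing.

    Returns the best point found, its value, and the best-so-far trace
    (which is non-increasing by construction).
    """
    names = list(bounds)
    widths = {k: config.proposal_frac * (bounds[k][1] - bounds[k][0]) for k in names}
    if x0 is None:
        x0 = {k: rng.uniform(*bounds[k]) for k in names}
    cur = dict(x0)
    cur_val = objective(cur)
    best, best_val = dict(cur), cur_val
    history = [best_val]
    temp = config.t0
    for _ in range(config.steps):
        prop = {
            k: _reflect(cur[k] + rng.normal(0.0, widths[k]), *bounds[k])
            for k in names
        }
        val = objective(prop)
        if val <= cur_val or rng.random() < np.exp(-(val - cur_val) / max(temp, 1e-12)):
            cur, cur_val = prop, val
            if val < best_val:
                best, best_val = dict(prop), val
        history.append(best_val)
        temp *= config.cooling
    return best, best_val, history


def fit_animal(
    animal: AnimalFitData | pd.DataFrame,
    spec: ModelSpec | str,
    schedule: Schedule,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 4,
    n_repeats: int = 200,
    anneal: AnnealConfig = AnnealConfig(),
    seed: int = 0,
    fitted_contingencies: Sequence[int] = (2, 3),
    smooth_sd: float = 2.25,
) -> FitResult:
    """Fit (alpha, gamma, omega) to one animal's error curves.

    Runs ``n_restarts`` annealing runs (at least 4) from random in-bounds
    starting points and returns the restart with minimal RMS error.  All
    objective evaluations share one simulation seed (derived from ``seed``)
    so that parameter changes, not simulation noise, drive the search.
    """
    if n_restarts < 4:
        raise ValueError("use at least 4 restarts")
    if isinstance(animal, pd.DataFrame):
        animal = AnimalFitData.from_frame(animal)
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    bounds = bounds or PARAM_BOUNDS
    sim_seed = seed

    def objective(x: dict[str, float]) -> float:
        return abc_objective(
            animal,
            spec,
            ModelParams(**x),
            schedule,
            n_repeats=n_repeats,
            seed=sim_seed,
            fitted_contingencies=fitted_contingencies,
            smooth_sd=smooth_sd,
        )

    restarts: list[tuple[ModelParams, float]] = []
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + 10_007 * (r + 1))
        best, best_val, _ = simulated_annealing(objective, bounds, rng, anneal)
        restarts.append((ModelParams(**best), best_val))
    if not restarts:
        raise RuntimeError("fit failed: no valid evaluations")
    best_params, best_rms = min(restarts, key=lambda t: t[1])
    return FitResult(
        params=best_params,
        rms=best_rms,
        restart_errors=restarts,
        seed=seed,
        fitted_contingencies=tuple(sorted(fitted_contingencies)),
        n_repeats=n_repeats,
        anneal=anneal,
    )


def fit_animal_batch(
    animal: AnimalFitData | pd.DataFrame,
    spec: ModelSpec | str,
    schedule: Schedule,
    n_fits: int = 20,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Repeat the fit ``n_fits`` times; report per-parameter median and IQR."""
    fits = [
        fit_animal(animal, spec, schedule, seed=seed + 131 * i, **kwargs)
        for i in range(n_fits)
    ]
    table = {
        k: np.array([getattr(f.params, k) for f in fits])
        for k in ("alpha", "gamma", "omega")
    }
    summary = {
        k: {
            "median": float(np.median(v)),
            "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
        }
        for k, v in table.items()
    }
    return {"fits": fits, "summary": summary}


# ---------------------------------------------------------------------------
# Reward-maximizing parameters
# ---------------------------------------------------------------------------

def _grid_axes(bounds: dict[str, tuple[float, float]], n: int) -> dict[str, np.ndarray]:
    return {k: np.linspace(lo, hi, n) for k, (lo, hi) in bounds.items()}


def reward_maximizing_params(
    spec: ModelSpec | str,
    schedule: Schedule,
    n_repeats: int = 50,
    seed: int = 0,
    grid_size: int = 5,
    refine: bool = True,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> tuple[ModelParams, float]:
    """Parameters maximizing mean total reward over the schedule.

    Coarse grid search (``grid_size`` points per parameter) followed by one
    local 3x3x3 refinement around the coarse optimum.  All evaluations use a
    common seed; exact ties resolve to the lowest grid index.  Returns the
    best parameters and their mean total reward.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    bounds = bounds or PARAM_BOUNDS

    def evaluate(p: ModelParams) -> float:
        res = run_batch(spec, p, schedule, n_repeats=n_repeats, seed=seed)
        return res.mean_total_reward()

    def search(axes: dict[str, np.ndarray]) -> tuple[ModelParams, float]:
        best_params, best_val = None, -np.inf
        for a in axes["alpha"]:
            for g in axes["gamma"]:
                for o in axes["omega"]:
                    p = ModelParams(alpha=float(a), gamma=float(g), omega=float(o))
                    val = evaluate(p)
                    if val > best_val:  # strict: ties keep the earlier point
                        best_params, best_val = p, val
        return best_params, best_val

    axes = _grid_axes(bounds, grid_size)
    best, best_val = search(axes)
    if refine:
        fine = {}
        for k in ("alpha", "gamma", "omega"):
            lo, hi = bounds[k]
            step = (hi - lo) / max(grid_size - 1, 1)
            c = getattr(best, k)
            fine[k] = np.unique(np.clip(np.array([c - step / 2, c, c + step / 2]), lo, hi))
        refined, refined_val = search(fine)
        if refined_val > best_val:
            best, best_val = refined, refined_val
    return best, best_val


def group_crossing(
    res: BatchResult, phase_idx: int, smooth_sd: float = 10.0, threshold: float = 0.75
) -> float:
    """75%-crossing visit of the repeat-averaged reward curve for one phase.

    The average uses all repeats still in the phase at each visit index; a
    curve that never crosses is censored at its final visit + 1.
    """
    mat = res.phase_reward_matrix(phase_idx)
    with np.errstate(invalid="ignore"):
        mean_curve = np.nanmean(mat, axis=0)
    mean_curve = mean_curve[~np.isnan(mean_curve)]
    sm = smooth_gaussian(mean_curve, smooth_sd)
    ci = crossing_index(sm, threshold)
    return float(ci) if ci is not None else float(len(sm) + 1)
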