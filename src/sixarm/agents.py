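"""Working-memory actor-critic REINFORCE agents for the six-arm task.

The agent family shares a common structure.  Its state is the pair
``(previous arm, current arm)`` — a one-step working memory — giving 43
enumerable states: 36 arm/arm pairs (six of which are same-arm pairs that can
never occur under play, since revisits are disallowed), 6 states with the
rest box as the previous location, and 1 rest-box start state.

Action propensities ``m(a, s)`` are a sum of components that differ between
model variants:

* **M1** — a state-dependent transition preference ``b(a, s)`` only;
* **M2** — M1 plus a location-independent dynamic arm preference ``b_i(a)``;
* **M3** — M2 plus dynamic neighbor preferences ``b_n1`` / ``b_n2`` applied to
  arms one or two positions away from the current arm (clipped at the track
  edges);
* **M3noArm** — M3 without the independent arm preference.

Propensities pass through a softmax with the current arm's probability forced
to zero.  Learning is REINFORCE within an actor-critic scheme: a table
``V(s)`` of state values yields the prediction error
``delta = r + gamma * V(s') - V(s)``, and every component is updated with a
single learning rate ``alpha`` and decays toward indifference with a single
forgetting rate ``omega``.

The functions in this module are the scalar reference implementation; bulk
simulation (hundreds of repeats) goes through :mod:`sixarm._engine`, which is
verified against these functions in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from sixarm.task import REST, Schedule, _check_arm, reward_exploration

#: Total number of agent states: 36 arm pairs + 6 rest-box pairs + 1 start.
N_STATES: int = 43

#: Arm-pair states (prev == cur) that are constructible but unreachable.
N_UNREACHABLE_STATES: int = 6

#: Fitting bounds for the three model parameters.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "gamma": (0.0, 0.999),
    "omega": (0.001, 0.015),
}


@dataclass(frozen=True)
class ModelParams:
    """The three agent parameters.

    alpha : learning rate in [0, 1]
    gamma : temporal discount factor in [0, 1)
    omega : forgetting rate (per-trial geometric decay toward indifference);
        fits constrain it to [0.001, 0.015], but any value in [0, 1] is a
        valid dynamical setting (omega = 0 disables forgetting).
    """

    alpha: float
    gamma: float
    omega: float

    def __post_init__(self) -> None:
        for name, val in (("alpha", self.alpha), ("gamma", self.gamma), ("omega", self.omega)):
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must be in [0, 1], got {self.omega}")

    def in_bounds(self, bounds: dict[str, tuple[float, float]] | None = None) -> bool:
        bounds = bounds or PARAM_BOUNDS
        return all(
            bounds[k][0] <= getattr(self, k) <= bounds[k][1]
            for k in ("alpha", "gamma", "omega")
        )

    def as_dict(self) -> dict[str, float]:
        return {"alpha": self.alpha, "gamma": self.gamma, "omega": self.omega}


@dataclass(frozen=True)
class ModelSpec:
    """Which propensity components a model variant includes."""

    name: str
    include_arm: bool
    include_neighbor: bool

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            return MODELS[name]
        except KeyError:
            raise ValueError(f"unknown model {name!r}; choose from {sorted(MODELS)}")


MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", include_arm=False, include_neighbor=False),
    "M2": ModelSpec("M2", include_arm=True, include_neighbor=False),
    "M3": ModelSpec("M3", include_arm=True, include_neighbor=True),
    "M3noArm": ModelSpec("M3noArm", include_arm=False, include_neighbor=True),
}


def state_index(prev_arm: int, cur_arm: int) -> int:
    """Map an ``(previous, current)`` location pair to a state index in 0..42.

    Arm/arm pairs occupy 0..35, (REST, arm) pairs 36..41, and the rest-box
    start state (REST, REST) is 42.  The current location may be REST only in
    the start state.
    """
    if cur_arm == REST:
        if prev_arm == REST:
            return 42
        raise ValueError("current location can be REST only in the start state")
    _check_arm(cur_arm)
    if prev_arm == REST:
        return 36 + (cur_arm - 1)
    _check_arm(prev_arm)
    return (prev_arm - 1) * 6 + (cur_arm - 1)


def state_from_index(index: int) -> tuple[int, int]:
    """Inverse of :func:`state_index`."""
    if not 0 <= index < N_STATES:
        raise ValueError(f"state index must be in 0..42, got {index}")
    if index == 42:
        return (REST, REST)
    if index >= 36:
        return (REST, index - 36 + 1)
    return (index // 6 + 1, index % 6 + 1)


def enumerate_states() -> list[tuple[int, int]]:
    """All 43 legal ``(previous, current)`` pairs in index order."""
    return [state_from_index(i) for i in range(N_STATES)]


@dataclass(frozen=True)
class AgentState:
    """The agent's working-memory state: previous and current location."""

    prev_arm: int
    cur_arm: int

    @property
    def index(self) -> int:
        return state_index(self.prev_arm, self.cur_arm)


@dataclass
class PropensitySet:
    """All plastic quantities of an agent.

    b_trans : (6, 43) state-dependent transition propensities b(a, s)
    b_arm : (6,) independent arm preferences b_i(a)
    b_n1, b_n2 : scalar neighbor preferences (one / two arms away)
    v : (43,) state values V(s)
    """

    b_trans: np.ndarray
    b_arm: np.ndarray
    b_n1: float
    b_n2: float
    v: np.ndarray

    def __post_init__(self) -> None:
        self.b_trans = np.asarray(self.b_trans, dtype=float)
        self.b_arm = np.asarray(self.b_arm, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.b_trans.shape != (6, N_STATES):
            raise ValueError(f"b_trans must be (6, {N_STATES}), got {self.b_trans.shape}")
        if self.b_arm.shape != (6,):
            raise ValueError(f"b_arm must be (6,), got {self.b_arm.shape}")
        if self.v.shape != (N_STATES,):
            raise ValueError(f"v must be ({N_STATES},), got {self.v.shape}")
        if not (
            np.all(np.isfinite(self.b_trans))
            and np.all(np.isfinite(self.b_arm))
            and np.isfinite(self.b_n1)
            and np.isfinite(self.b_n2)
            and np.all(np.isfinite(self.v))
        ):
            raise ValueError("propensities must be finite")

    @classmethod
    def zeros(cls) -> "PropensitySet":
        return cls(
            b_trans=np.zeros((6, N_STATES)),
            b_arm=np.zeros(6),
            b_n1=0.0,
            b_n2=0.0,
            v=np.zeros(N_STATES),
        )

    def copy(self) -> "PropensitySet":
        return PropensitySet(
            b_trans=self.b_trans.copy(),
            b_arm=self.b_arm.copy(),
            b_n1=float(self.b_n1),
            b_n2=float(self.b_n2),
            v=self.v.copy(),
        )

    def allclose(self, other: "PropensitySet", **kw) -> bool:
        return (
            np.allclose(self.b_trans, other.b_trans, **kw)
            and np.allclose(self.b_arm, other.b_arm, **kw)
            and np.allclose(self.b_n1, other.b_n1, **kw)
            and np.allclose(self.b_n2, other.b_n2, **kw)
            and np.allclose(self.v, other.v, **kw)
        )


def neighbor_arms(cur_arm: int, distance: int) -> tuple[int, ...]:
    """In-range arms ``cur_arm +/- distance``; empty if the agent is at REST.

    At the track edges only the in-range side exists, so the neighbor
    preference applies in one direction only.
    """
    if cur_arm == REST:
        return ()
    return tuple(a for a in (cur_arm - distance, cur_arm + distance) if 1 <= a <= 6)


def total_propensity(spec: ModelSpec, pset: PropensitySet, state: AgentState) -> np.ndarray:
    """The summed propensity vector m(a, s) over target arms 1..6."""
    m = pset.b_trans[:, state.index].copy()
    if spec.include_arm:
        m = m + pset.b_arm
    if spec.include_neighbor:
        for a in neighbor_arms(state.cur_arm, 1):
            m[a - 1] += pset.b_n1
        for a in neighbor_arms(state.cur_arm, 2):
            m[a - 1] += pset.b_n2
    return m


def action_probabilities(m: np.ndarray, cur_arm: int) -> np.ndarray:
    """Softmax of the propensities with the current arm excluded.

    The probability of revisiting the current arm is exactly zero and the
    remainder sums to one.  The result is invariant to adding a constant to
    ``m`` (the maximum is subtracted before exponentiation).  From the rest
    box all six arms are available.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (6,):
        raise ValueError(f"m must be a 6-vector, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("propensities must be finite")
    z = m.copy()
    if cur_arm != REST:
        _check_arm(cur_arm)
        z[cur_arm - 1] = -np.inf
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def prediction_error(reward: float, v_t: float, v_t1: float, gamma: float) -> float:
    """Temporal-difference prediction error delta = r + gamma*V(s') - V(s)."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must be in [0, 1), got {gamma}")
    return reward + gamma * v_t1 - v_t


def apply_updates(
    spec: ModelSpec,
    pset: PropensitySet,
    state: AgentState,
    choice: int,
    probs: np.ndarray,
    delta: float,
    params: ModelParams,
) -> PropensitySet:
    """One REINFORCE/TD update of every propensity component and V.

    All entries decay by ``(1 - omega)``; the REINFORCE increment
    ``alpha * delta * (chosen-indicator - p)`` is added to the transition
    propensities of the visited state, to the arm preferences (for every
    arm), and to the neighbor preferences using the summed probability mass
    of the eligible neighbor arms.  ``V`` receives ``alpha * delta`` at the
    visited state.  A single ``(alpha, omega)`` pair governs all rules.
    """
    _check_arm(choice)
    probs = np.asarray(probs, dtype=float)
    alpha, omega = params.alpha, params.omega
    decay = 1.0 - omega
    s = state.index

    inc = alpha * delta * (-probs)
    inc[choice - 1] = alpha * delta * (1.0 - probs[choice - 1])

    b_trans = pset.b_trans * decay
    b_trans[:, s] += inc

    b_arm = pset.b_arm * decay
    if spec.include_arm:
        b_arm += inc

    b_n1 = pset.b_n1 * decay
    b_n2 = pset.b_n2 * decay
    if spec.include_neighbor:
        for dist, cur in ((1, "b_n1"), (2, "b_n2")):
            arms = neighbor_arms(state.cur_arm, dist)
            p_mass = float(sum(probs[a - 1] for a in arms))
            chosen = 1.0 if choice in arms else 0.0
            upd = alpha * delta * (chosen - p_mass)
            if dist == 1:
                b_n1 += upd
            else:
                b_n2 += upd

    v = pset.v * decay
    v[s] += alpha * delta

    return PropensitySet(b_trans=b_trans, b_arm=b_arm, b_n1=b_n1, b_n2=b_n2, v=v)


def run_agent(
    spec: ModelSpec | str,
    params: ModelParams,
    schedule: Schedule,
    n_repeats: int = 200,
    seed: int = 0,
    init: PropensitySet | None = None,
):
    """Run ``n_repeats`` independent seeded episodes over the full schedule.

    Repeat ``k`` draws from a generator seeded with ``seed + k``, so the
    averaged behavior is reproducible bit-exactly and a batch run agrees
    with running each repeat on its own.  Returns a
    :class:`sixarm._engine.BatchResult`.
    """
    from sixarm._engine import run_batch

    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    return run_batch(spec, params, schedule, n_repeats=n_repeats, seed=seed, init=init)


def force_trajectory(
    spec: ModelSpec | str,
    params: ModelParams,
    sessions: Sequence[Sequence[int]],
    pset: PropensitySet | None = None,
) -> PropensitySet:
    """Drive the agent along observed exploration visits, learning as it goes.

    The agent's choices are overridden by the given arm sequences (one per
    session) while rewards, prediction errors, and all propensity updates
    proceed exactly as in free play under the exploration reward rule.  Used
    to set an agent's initial condition from an animal's exploratory period.
    No randomness is consumed.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    pset = pset.copy() if pset is not None else PropensitySet.zeros()
    for session in sessions:
        prev, cur = REST, REST
        for arm in session:
            _check_arm(arm)
            if arm == cur:
                raise ValueError("forced trajectory revisits the current arm")
            state = AgentState(prev, cur)
            m = total_propensity(spec, pset, state)
            probs = action_probabilities(m, cur)
            rewarded = reward_exploration(cur, arm)
            s_next = AgentState(cur, arm)
            delta = prediction_error(
                float(rewarded), pset.v[state.index], pset.v[s_next.index], params.gamma
            )
            pset = apply_updates(spec, pset, state, arm, probs, delta, params)
            prev, cur = cur, arm
    return pset
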