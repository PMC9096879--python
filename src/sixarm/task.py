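"""Reward rules and session scheduling for the six-arm spatial alternation task.

The track has six parallel arms (numbered 1-6) joined by a back corridor, with
a reward well at the end of each arm; animals enter each session from a rest
box.  Behavior proceeds in two phases:

* **Exploration** — any arm visit is rewarded unless it repeats the
  immediately preceding arm; a session ends after a fixed number of rewards.
* **Alternation** — a *contingency* designates three arms (outer, center,
  outer).  Center visits are rewarded iff the preceding visited arm was not
  the center.  Outer visits are rewarded iff the preceding arm was the center
  and the most recent outer arm visited before that center visit was not the
  current one (with an exception at the start of a session, before any outer
  arm of the contingency has been visited).  A session ends after a fixed
  number of center-arm visits plus one further visit.

All rules here are deterministic functions of the visit sequence, so replaying
a trajectory reproduces its reward flags exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Sequence

import yaml

#: Sentinel for "no arm": the rest box before the first visit of a session.
REST: int = 0

#: Sentinel for "no outer arm visited yet".
NONE_ARM: int = -1

ARMS = (1, 2, 3, 4, 5, 6)

PhaseKind = Literal["explore", "alt"]
TrialType = Literal["inbound", "outbound"]

#: Contingency order used in the study: 234, 123, 345, 246, 234, 456.
DEFAULT_CONTINGENCY_ORDER = ("234", "123", "345", "246", "234", "456")


class InvalidArmError(ValueError):
    """An arm id outside 1..6 (or an illegal REST) was supplied."""


class InvalidChoiceError(ValueError):
    """A policy chose the arm it is currently on; revisits are disallowed."""


def _check_arm(arm: int) -> int:
    if arm not in ARMS:
        raise InvalidArmError(f"arm must be in 1..6, got {arm!r}")
    return arm


@dataclass(frozen=True)
class Contingency:
    """A rewarded arm triple (outer-low, center, outer-high).

    The center is the middle listed arm; only these three arms can ever
    deliver reward while the contingency is active.
    """

    arms: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.arms) != 3 or len(set(self.arms)) != 3:
            raise ValueError(f"contingency needs three distinct arms, got {self.arms}")
        for a in self.arms:
            _check_arm(a)

    @classmethod
    def from_label(cls, label: str) -> "Contingency":
        """Parse a label such as ``"234"`` into a contingency."""
        if len(label) != 3 or not label.isdigit():
            raise ValueError(f"bad contingency label {label!r}")
        return cls(tuple(int(c) for c in label))  # type: ignore[arg-type]

    @property
    def label(self) -> str:
        return "".join(str(a) for a in self.arms)

    @property
    def center(self) -> int:
        return self.arms[1]

    @property
    def outers(self) -> tuple[int, int]:
        return (self.arms[0], self.arms[2])


@dataclass(frozen=True)
class TaskState:
    """Bookkeeping carried across visits within an alternation session.

    ``last_outer_before_center`` is the most recent outer arm visited prior
    to the most recent center visit (``NONE_ARM`` if there was none); it is
    the arm whose repetition makes an outer visit unrewarded.
    """

    contingency: Contingency
    last_arm: int = REST
    last_outer: int = NONE_ARM
    last_outer_before_center: int = NONE_ARM
    center_visits: int = 0

    @classmethod
    def fresh(cls, contingency: Contingency) -> "TaskState":
        return cls(contingency=contingency)


def reward_exploration(prev_arm: int, arm: int) -> bool:
    """Exploration rule: rewarded iff not a repeat of the preceding arm.

    ``prev_arm`` may be :data:`REST` at the start of a session, in which case
    any arm is rewarded.
    """
    _check_arm(arm)
    if prev_arm != REST:
        _check_arm(prev_arm)
    return arm != prev_arm


def alternation_step(state: TaskState, arm: int) -> tuple[bool, TaskState]:
    """Apply one arm visit under the alternation rule.

    Returns the reward flag and the updated task state.  Visits to arms
    outside the contingency are never rewarded but still update the
    "immediately preceding arm" memory of the rule.
    """
    _check_arm(arm)
    cont = state.contingency
    center = cont.center
    rewarded = False
    new_center_visits = state.center_visits
    last_outer = state.last_outer
    lobc = state.last_outer_before_center

    if arm == center:
        rewarded = state.last_arm != center
        new_center_visits += 1
        lobc = state.last_outer
    elif arm in cont.outers:
        rewarded = (
            state.last_arm == center and state.last_outer_before_center != arm
        )
        last_outer = arm

    new_state = replace(
        state,
        last_arm=arm,
        last_outer=last_outer,
        last_outer_before_center=lobc,
        center_visits=new_center_visits,
    )
    return rewarded, new_state


def classify_trial(contingency: Contingency, from_arm: int) -> TrialType:
    """A trial is outbound iff it starts from the contingency's center arm.

    Trials starting from any other arm — including arms outside the
    contingency — are inbound.
    """
    _check_arm(from_arm)
    return "outbound" if from_arm == contingency.center else "inbound"


def run_session(
    contingency: Contingency,
    policy: Callable[[int, int], int],
    limit: int,
    kind: PhaseKind = "alt",
) -> list[tuple[int, bool]]:
    """Simulate a single session under ``policy``.

    ``policy(prev_arm, cur_arm) -> arm`` chooses the next arm given the
    previous and current location (both :data:`REST` at session start).  For
    alternation sessions the session ends after ``limit`` center visits plus
    one further visit; for exploration sessions it ends once ``limit`` rewards
    have been delivered.

    Returns the list of ``(arm, rewarded)`` visits.
    """
    if limit <= 0:
        raise ValueError("limit must be positive")
    visits: list[tuple[int, bool]] = []
    prev, cur = REST, REST
    state = TaskState.fresh(contingency)
    n_rewards = 0
    while True:
        arm = policy(prev, cur)
        _check_arm(arm)
        if arm == cur:
            raise InvalidChoiceError("policy revisited the current arm")
        if kind == "alt":
            rewarded, state = alternation_step(state, arm)
        else:
            rewarded = reward_exploration(cur, arm)
        visits.append((arm, rewarded))
        n_rewards += rewarded
        prev, cur = cur, arm
        if kind == "alt":
            # End at the first visit after the limit-th center visit,
            # regardless of which arm that closing visit lands on.
            if state.center_visits >= limit and arm != contingency.center:
                break
        else:
            if n_rewards >= limit:
                break
    return visits


@dataclass(frozen=True)
class Phase:
    """One block of a schedule: an exploration or alternation phase.

    ``session_limits`` holds one entry per session: rewards per session for
    exploration phases, center visits per session for alternation phases.
    """

    kind: PhaseKind
    session_limits: tuple[int, ...]
    contingency: Contingency | None = None

    def __post_init__(self) -> None:
        if not self.session_limits or any(l <= 0 for l in self.session_limits):
            raise ValueError("session limits must be positive")
        if self.kind == "alt" and self.contingency is None:
            raise ValueError("alternation phases need a contingency")

    @property
    def n_sessions(self) -> int:
        return len(self.session_limits)


@dataclass(frozen=True)
class Schedule:
    """An ordered list of phases the agent (or animal) runs through."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule needs at least one phase")

    @property
    def alternation_phases(self) -> list[Phase]:
        return [p for p in self.phases if p.kind == "alt"]

    @classmethod
    def default(
        cls,
        contingency_order: Sequence[str] = DEFAULT_CONTINGENCY_ORDER,
        explore_sessions: int = 15,
        rewards_per_explore_session: int = 25,
        days_per_contingency: int = 3,
        sessions_per_day: int = 3,
    ) -> "Schedule":
        """The study-style schedule with fixed per-contingency budgets.

        Sessions run three to a day.  The first alternation day of the first
        contingency uses 10 center visits per session, the first day of every
        other contingency (and the second day of the first) uses 20, and all
        later days use 40.
        """
        phases: list[Phase] = []
        if explore_sessions:
            phases.append(
                Phase(
                    kind="explore",
                    session_limits=(rewards_per_explore_session,) * explore_sessions,
                )
            )
        for i, label in enumerate(contingency_order):
            day_limits = []
            for day in range(days_per_contingency):
                if i == 0 and day == 0:
                    lim = 10
                elif (i == 0 and day == 1) or (i > 0 and day == 0):
                    lim = 20
                else:
                    lim = 40
                day_limits.extend([lim] * sessions_per_day)
            phases.append(
                Phase(
                    kind="alt",
                    session_limits=tuple(day_limits),
                    contingency=Contingency.from_label(label),
                )
            )
        return cls(tuple(phases))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = []
        for p in self.phases:
            d: dict = {"kind": p.kind, "session_limits": list(p.session_limits)}
            if p.contingency is not None:
                d["contingency"] = p.contingency.label
            out.append(d)
        return {"phases": out}

    @classmethod
    def from_dict(cls, d: dict) -> "Schedule":
        phases = []
        for p in d["phases"]:
            cont = (
                Contingency.from_label(str(p["contingency"]))
                if p.get("contingency")
                else None
            )
            phases.append(
                Phase(
                    kind=p["kind"],
                    session_limits=tuple(int(x) for x in p["session_limits"]),
                    contingency=cont,
                )
            )
        return cls(tuple(phases))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Schedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def perfect_alternation_policy(contingency: Contingency) -> Callable[[int, int], int]:
    """A deterministic policy that is rewarded on every visit.

    Starting from the rest box it goes straight to the center arm, then runs
    outer, center, other outer, center, ... (e.g. 3-4-3-2-3-4-3 for
    contingency 234), which satisfies both the center and the outer rules on
    every single visit, including the first.
    """
    low, center, high = contingency.arms

    def policy(prev: int, cur: int) -> int:
        if cur != center:  # includes the rest box and any non-center arm
            return center
        # At center: go to the outer arm not most recently visited.
        return low if prev == high else high

    return policy
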