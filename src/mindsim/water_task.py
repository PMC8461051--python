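"""The Ask-for-Water environment.

A newcomer to a village must find water by talking to villagers (NPCs). The
village culture ties formality to status: old and young villagers prefer
formal address, middle-aged villagers informal. The player holds a graded
belief in [-2, 2] per age class about whether that class likes formality;
greeting or asking with the wrong formality draws a negative reaction, and
each reaction is an opportunity for the player's belief about that age class
to move one step toward the true value.

This module owns the *real-world* dynamics: what actually happens when an
action is taken, which reactions NPCs give, when the water location is
revealed, and how beliefs actually update (the update probabilities differ
by mindset, implementing confirmation bias for the fixed mindset and an
uncertainty-peaked update for the malleable one). The players' *subjective*
expectations live in :mod:`mindsim.profiles`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .mdp import StateSpace

__all__ = [
    "Action",
    "AgeClass",
    "Valence",
    "GameState",
    "Culture",
    "Feedback",
    "NPC",
    "EnvironmentConfig",
    "TRUE_CULTURE",
    "STATE_SPACE",
    "ACTIONS",
    "BELIEF_UPDATE_TABLE",
    "available_actions",
    "belief_update_probability",
    "real_world_step",
    "roster",
]


class Action(enum.IntEnum):
    SELECT_NPC_YOUNG = 0
    SELECT_NPC_MID = 1
    SELECT_NPC_OLD = 2
    GREET_FORMAL = 3
    GREET_INFORMAL = 4
    ASK_FORMAL = 5
    ASK_INFORMAL = 6
    LEAVE = 7
    STOP = 8


ACTIONS: tuple[Action, ...] = tuple(Action)

SELECT_ACTIONS = (Action.SELECT_NPC_YOUNG, Action.SELECT_NPC_MID, Action.SELECT_NPC_OLD)
GREET_ACTIONS = (Action.GREET_FORMAL, Action.GREET_INFORMAL)
ASK_ACTIONS = (Action.ASK_FORMAL, Action.ASK_INFORMAL)
DIALOG_ACTIONS = GREET_ACTIONS + ASK_ACTIONS
FORMAL_ACTIONS = (Action.GREET_FORMAL, Action.ASK_FORMAL)


class AgeClass(enum.IntEnum):
    NONE = 0
    YOUNG = 1
    MID = 2
    OLD = 3


_SELECT_TO_AGE = {
    Action.SELECT_NPC_YOUNG: AgeClass.YOUNG,
    Action.SELECT_NPC_MID: AgeClass.MID,
    Action.SELECT_NPC_OLD: AgeClass.OLD,
}


class Valence(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONE = "none"


@dataclass(frozen=True)
class GameState:
    """The nine discrete state variables.

    The three ``*_likes_formal`` fields are the player's graded beliefs
    (-2 certain dislike ... +2 certain like); the remaining fields are the
    situation and quest status. The same structure serves as the player's
    cognitive state and as the real-world state.
    """

    old_likes_formal: int
    mid_likes_formal: int
    young_likes_formal: int
    in_conversation: int
    npc_age: AgeClass
    greeted: int
    asked: int
    npc_happy: int
    got_water: int

    def __post_init__(self) -> None:
        for name in ("old_likes_formal", "mid_likes_formal", "young_likes_formal"):
            if not -2 <= getattr(self, name) <= 2:
                raise ValueError(f"{name} outside [-2, 2]")
        for name in ("in_conversation", "greeted", "asked", "npc_happy", "got_water"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        object.__setattr__(self, "npc_age", AgeClass(self.npc_age))

    def validate(self) -> None:
        """Check the consistency invariants that valid play maintains."""
        if (self.npc_age == AgeClass.NONE) != (self.in_conversation == 0):
            raise ValueError("npc_age must be NONE iff not in conversation")
        if self.in_conversation == 0 and (self.greeted or self.asked or self.npc_happy):
            raise ValueError("conversation flags must be 0 outside a conversation")

    def belief(self, age: AgeClass) -> int:
        return {
            AgeClass.OLD: self.old_likes_formal,
            AgeClass.MID: self.mid_likes_formal,
            AgeClass.YOUNG: self.young_likes_formal,
        }[age]

    @property
    def beliefs(self) -> tuple[int, int, int]:
        """(old, mid, young) belief values."""
        return (self.old_likes_formal, self.mid_likes_formal, self.young_likes_formal)

    def with_belief(self, age: AgeClass, value: int) -> "GameState":
        key = {
            AgeClass.OLD: "old_likes_formal",
            AgeClass.MID: "mid_likes_formal",
            AgeClass.YOUNG: "young_likes_formal",
        }[age]
        return replace(self, **{key: value})

    def as_tuple(self) -> tuple[int, ...]:
        return (
            self.old_likes_formal,
            self.mid_likes_formal,
            self.young_likes_formal,
            self.in_conversation,
            int(self.npc_age),
            self.greeted,
            self.asked,
            self.npc_happy,
            self.got_water,
        )

    @classmethod
    def from_tuple(cls, t) -> "GameState":
        return cls(*t)


#: Full product space of the nine variables: 5*5*5*2*4*2*2*2*2 = 32,000.
STATE_SPACE = StateSpace(
    variables=(
        ("OLD_LIKES_FORMAL", -2, 2),
        ("MID_LIKES_FORMAL", -2, 2),
        ("YOUNG_LIKES_FORMAL", -2, 2),
        ("IN_CONVERSATION", 0, 1),
        ("NPC_AGE", 0, 3),
        ("GREETED", 0, 1),
        ("ASKED", 0, 1),
        ("NPC_HAPPY", 0, 1),
        ("GOT_WATER", 0, 1),
    )
)


@dataclass(frozen=True)
class Culture:
    """Which age classes prefer formal address."""

    likes_formal: Mapping[AgeClass, bool]

    def correct_belief(self, age: AgeClass) -> int:
        return 2 if self.likes_formal[age] else -2

    @property
    def correct_beliefs(self) -> tuple[int, int, int]:
        """(old, mid, young) fully-confident correct belief values."""
        return (
            self.correct_belief(AgeClass.OLD),
            self.correct_belief(AgeClass.MID),
            self.correct_belief(AgeClass.YOUNG),
        )


#: The true village culture: high status (old, young) formal, middle informal.
TRUE_CULTURE = Culture(
    likes_formal={AgeClass.YOUNG: True, AgeClass.MID: False, AgeClass.OLD: True}
)


@dataclass(frozen=True)
class Feedback:
    valence: Valence
    tag: str = "none"  # narrative only: nice_reply / subtle_frown / none
    age: AgeClass = AgeClass.NONE


NO_FEEDBACK = Feedback(valence=Valence.NONE)


@dataclass(frozen=True)
class NPC:
    name: str
    gender: str
    age: AgeClass
    profession: str


_ROSTER = (
    NPC("Stan", "male", AgeClass.YOUNG, "Student"),
    NPC("Belle", "female", AgeClass.YOUNG, "Mayor"),
    NPC("Emma", "female", AgeClass.MID, "Sheriff"),
    NPC("Mick", "male", AgeClass.MID, "Pilot"),
    NPC("Brim", "female", AgeClass.OLD, "Nanosmith"),
    NPC("Clayton", "male", AgeClass.OLD, "Farmer"),
)


def roster() -> tuple[NPC, ...]:
    """The six villagers, two per age class (narrative annotation only)."""
    return _ROSTER


#: Probability that one piece of feedback actually moves a belief one step
#: toward its correct value, keyed on the current value expressed in the
#: frame where the correct value is +2. The fixed column rises toward the
#: correct value (confirmation bias: feedback nearer the held belief is
#: easier to accept); the malleable column peaks at complete uncertainty.
BELIEF_UPDATE_TABLE: dict[int, dict[str, float]] = {
    -2: {"fixed": 0.20, "malleable": 0.30},
    -1: {"fixed": 0.40, "malleable": 0.60},
    0: {"fixed": 0.60, "malleable": 0.95},
    1: {"fixed": 0.80, "malleable": 0.60},
    2: {"fixed": 0.0, "malleable": 0.0},
}


@dataclass(frozen=True)
class EnvironmentConfig:
    """Real-world parameters of the task.

    ``p_reveal_happy`` / ``p_reveal_unhappy`` are the probabilities that an
    NPC reveals the water location when asked while happy / unhappy; a happy
    NPC must be at least as forthcoming. ``max_steps`` caps an episode
    (force-terminated with end reason "cap" rather than a STOP action).
    """

    p_reveal_happy: float = 0.4
    p_reveal_unhappy: float = 0.05
    max_steps: int = 50
    culture: Culture = TRUE_CULTURE
    update_table: Mapping[int, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_reveal_unhappy <= self.p_reveal_happy <= 1:
            raise ValueError("need 0 <= p_reveal_unhappy <= p_reveal_happy <= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    @property
    def table(self) -> Mapping[int, Mapping[str, float]]:
        return self.update_table if self.update_table is not None else BELIEF_UPDATE_TABLE


def initial_situation(beliefs: tuple[int, int, int]) -> GameState:
    """Out-of-conversation start state with the given (old, mid, young) beliefs."""
    return GameState(*beliefs, 0, AgeClass.NONE, 0, 0, 0, 0)


def available_actions(state: GameState) -> tuple[Action, ...]:
    """Actions available in a state (total function over valid states)."""
    if state.in_conversation:
        if state.got_water:
            return (Action.LEAVE,)
        if not state.greeted:
            return (Action.GREET_FORMAL, Action.GREET_INFORMAL, Action.LEAVE)
        return (Action.ASK_FORMAL, Action.ASK_INFORMAL, Action.LEAVE)
    return SELECT_ACTIONS + (Action.STOP,)


def belief_update_probability(
    mindset: str,
    age: AgeClass,
    current_value: int,
    culture: Culture = TRUE_CULTURE,
    table: Mapping[int, Mapping[str, float]] | None = None,
) -> float:
    """Probability that feedback about ``age`` moves the belief one step.

    The table is written in the frame where the correct value is +2; for an
    age class whose correct value is -2 the current value is mirrored
    (value v looks up row -v). A belief already at its correct value cannot
    be updated further.
    """
    if not -2 <= current_value <= 2:
        raise ValueError("current_value outside [-2, 2]")
    table = BELIEF_UPDATE_TABLE if table is None else table
    row = current_value if culture.likes_formal[age] else -current_value
    probs = table[row]
    if mindset not in probs:
        raise KeyError(f"unknown mindset label {mindset!r}")
    return float(probs[mindset])


def _leave(state: GameState) -> GameState:
    return replace(
        state,
        in_conversation=0,
        npc_age=AgeClass.NONE,
        greeted=0,
        asked=0,
        npc_happy=0,
    )


def real_world_step(
    state: GameState,
    action: Action,
    profile,
    env: EnvironmentConfig,
    rng: np.random.Generator,
) -> tuple[GameState, Feedback]:
    """Apply one action to the real world; returns (next state, feedback).

    Greets and asks each trigger the reaction rule: the NPC is happy iff the
    chosen formality matches the true culture for its age class, yielding
    positive ("nice reply") or negative ("subtle frown") feedback. Asks
    additionally reveal the water with probability ``p_reveal_happy`` /
    ``p_reveal_unhappy`` depending on the NPC's mood after the ask. Every
    piece of feedback then gives one chance (``belief_update_probability``)
    for the concerned belief to move one step toward its true value. STOP
    returns the state unchanged; the caller marks the episode terminal.
    """
    acts = available_actions(state)
    if action not in acts:
        raise ValueError(f"action {action.name} unavailable in state {state}")

    if action == Action.STOP:
        return state, NO_FEEDBACK
    if action in SELECT_ACTIONS:
        return (
            replace(state, in_conversation=1, npc_age=_SELECT_TO_AGE[action]),
            NO_FEEDBACK,
        )
    if action == Action.LEAVE:
        return _leave(state), NO_FEEDBACK

    # Greet or ask, directed at the current NPC.
    age = state.npc_age
    if age == AgeClass.NONE:  # unreachable in valid play; defensive no-op
        flags = {"greeted": 1} if action in GREET_ACTIONS else {"asked": 1}
        return replace(state, **flags), NO_FEEDBACK
    formal = action in FORMAL_ACTIONS
    happy = formal == env.culture.likes_formal[age]
    valence = Valence.POSITIVE if happy else Valence.NEGATIVE
    tag = "nice_reply" if happy else "subtle_frown"
    new = replace(state, npc_happy=int(happy))
    if action in GREET_ACTIONS:
        new = replace(new, greeted=1)
    else:
        new = replace(new, asked=1)
        if not new.got_water:
            p = env.p_reveal_happy if happy else env.p_reveal_unhappy
            if rng.random() < p:
                new = replace(new, got_water=1)
    # Feedback gives the belief one chance to move toward the true value.
    b = new.belief(age)
    correct = env.culture.correct_belief(age)
    if b != correct:
        p_up = belief_update_probability(
            profile.label, age, b, env.culture, env.table
        )
        if rng.random() < p_up:
            new = new.with_belief(age, b + (1 if correct > b else -1))
    return new, Feedback(valence=valence, tag=tag, age=age)
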