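"""The two cultural-mindset cognitive profiles.

A profile bundles what distinguishes a fixed from a malleable mindset in the
model: where their beliefs start, how much knowing the culture is worth to
them relative to finding water, how costly time feels, and how they *expect*
their own beliefs to change — the subjective transition model the planner
runs on, as opposed to the real-world dynamics in :mod:`mindsim.water_task`.

Fixed mindset: starts with confident (partly wrong) beliefs, values water
over cultural knowledge, pays a high time cost, and does not expect to learn
from an interaction unless completely uncertain (belief exactly 0).

Malleable mindset: starts agnostic (all beliefs 0), values full cultural
knowledge above the water itself, pays a lower time cost, and expects to
learn whenever a belief is not yet at full strength (|belief| < 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .mdp import RewardModel, StateSpace, TransitionModel
from .water_task import (
    ACTIONS,
    Action,
    AgeClass,
    EnvironmentConfig,
    GameState,
    STATE_SPACE,
    available_actions,
    initial_situation,
)
from . import water_task

__all__ = [
    "MindsetProfile",
    "FIXED_PROFILE",
    "MALLEABLE_PROFILE",
    "PROFILES",
    "belief_strength",
    "terminal_reward",
    "subjective_transition",
    "build_cognitive_mdp",
]


@dataclass(frozen=True)
class MindsetProfile:
    """Parameters of one mindset.

    ``initial_beliefs`` is (old, mid, young). ``belief_reward_bands`` maps
    total belief strength s = sum |belief| at game end to a reward:
    0 < s < 3 -> bands[0], 3 <= s < 6 -> bands[1], s == 6 -> bands[2]
    (s == 0 earns nothing). ``time_cost`` (negative) accrues on every move.
    ``subjective_update`` selects how the planner expects its own beliefs to
    move: "mindset_rule" (the threshold rules described above) or "real_world_table"
    (reuse the real-world update probabilities).
    """

    label: str
    initial_beliefs: tuple[int, int, int]
    belief_reward_bands: tuple[float, float, float]
    time_cost: float
    water_reward: float = 5.0
    subjective_update: str = "mindset_rule"

    def __post_init__(self) -> None:
        if self.label not in ("fixed", "malleable"):
            raise ValueError(f"unknown mindset label {self.label!r}")
        if self.time_cost > 0:
            raise ValueError("time_cost must be <= 0")
        if self.subjective_update not in ("mindset_rule", "real_world_table"):
            raise ValueError(f"unknown subjective_update {self.subjective_update!r}")

    def initial_state(self) -> GameState:
        return initial_situation(self.initial_beliefs)

    def expects_update(self, belief: int) -> bool:
        """Does this mindset expect feedback to move a belief at this value?"""
        if self.label == "fixed":
            return belief == 0
        return abs(belief) < 2


FIXED_PROFILE = MindsetProfile(
    label="fixed",
    initial_beliefs=(2, 1, -2),
    belief_reward_bands=(0.5, 1.5, 3.5),
    time_cost=-0.75,
)

MALLEABLE_PROFILE = MindsetProfile(
    label="malleable",
    initial_beliefs=(0, 0, 0),
    belief_reward_bands=(1.0, 3.0, 6.0),
    time_cost=-0.5,
)

PROFILES: Mapping[str, MindsetProfile] = {
    "fixed": FIXED_PROFILE,
    "malleable": MALLEABLE_PROFILE,
}


def belief_strength(beliefs) -> int:
    """Total confidence sum |belief| over the three age-class beliefs (0..6)."""
    out = 0
    for b in beliefs:
        if not -2 <= b <= 2:
            raise ValueError("belief outside [-2, 2]")
        out += abs(b)
    return out


def terminal_reward(profile: MindsetProfile, final_state: GameState) -> float:
    """End-of-play reward: water plus the belief-strength band.

    The per-move time cost is *not* included here; it accrues during play.
    """
    s = belief_strength(final_state.beliefs)
    if s == 0:
        band = 0.0
    elif s < 3:
        band = profile.belief_reward_bands[0]
    elif s < 6:
        band = profile.belief_reward_bands[1]
    else:
        band = profile.belief_reward_bands[2]
    return profile.water_reward * final_state.got_water + band


def _subjective_happy_prob(belief: int, formal: bool) -> float:
    """Subjective P(NPC pleased) from the player's own belief.

    Belief b maps linearly onto P(this age class likes formality) = (b+2)/4;
    the NPC is expected to be pleased iff the chosen formality matches.
    """
    p_likes = (belief + 2) / 4
    return p_likes if formal else 1 - p_likes


def _expected_moves(profile: MindsetProfile, belief: int, direction: int) -> list[tuple[int, float]]:
    """Subjective belief outcomes [(new value, prob)] given evidence direction."""
    if profile.subjective_update == "mindset_rule":
        p_move = 1.0 if profile.expects_update(belief) else 0.0
    else:  # real_world_table: frame the update table along the evidence direction
        row = belief * direction
        p_move = water_task.BELIEF_UPDATE_TABLE[row][profile.label]
    target = belief + direction
    if not -2 <= target <= 2:
        p_move = 0.0
    if p_move == 0.0:
        return [(belief, 1.0)]
    if p_move == 1.0:
        return [(target, 1.0)]
    return [(target, p_move), (belief, 1.0 - p_move)]


def subjective_transition(
    profile: MindsetProfile,
    state: GameState,
    action: Action,
    env: EnvironmentConfig,
) -> list[tuple[GameState, float]]:
    """The player's internal model of what an action will do.

    Navigation (select / leave / stop) is expected to work deterministically.
    For a greet or ask, the player expects the NPC to be pleased with the
    probability implied by their own belief; pleasure or displeasure then
    constitutes evidence for / against formality, and the belief is expected
    to move one step in the evidence direction according to the mindset's
    update expectation. Asks are expected to reveal the water with the same
    reveal probabilities the real world uses (shared basic reasoning).
    """
    acts = available_actions(state)
    if action not in acts:
        raise ValueError(f"action {action.name} unavailable in state {state}")
    if action in water_task.SELECT_ACTIONS:
        age = water_task._SELECT_TO_AGE[action]
        return [(replace(state, in_conversation=1, npc_age=age), 1.0)]
    if action == Action.LEAVE:
        return [(water_task._leave(state), 1.0)]
    if action == Action.STOP:
        return [(state, 1.0)]

    age = state.npc_age
    if age == AgeClass.NONE:  # invalid in-conversation state; inert flag set
        flags = {"greeted": 1} if action in water_task.GREET_ACTIONS else {"asked": 1}
        return [(replace(state, **flags), 1.0)]
    formal = action in water_task.FORMAL_ACTIONS
    b = state.belief(age)
    p_happy = _subjective_happy_prob(b, formal)
    is_ask = action in water_task.ASK_ACTIONS
    flag = {"asked": 1} if is_ask else {"greeted": 1}

    outcomes: dict[GameState, float] = {}

    def add(s: GameState, p: float) -> None:
        if p > 0:
            outcomes[s] = outcomes.get(s, 0.0) + p

    for happy, p_mood in ((1, p_happy), (0, 1 - p_happy)):
        if p_mood <= 0:
            continue
        base = replace(state, npc_happy=happy, **flag)
        # pleased + formal or displeased + informal => evidence for formality
        direction = 1 if (bool(happy) == formal) else -1
        for new_b, p_b in _expected_moves(profile, b, direction):
            s_b = base.with_belief(age, new_b)
            if is_ask and not state.got_water:
                p_reveal = env.p_reveal_happy if happy else env.p_reveal_unhappy
                add(replace(s_b, got_water=1), p_mood * p_b * p_reveal)
                add(s_b, p_mood * p_b * (1 - p_reveal))
            else:
                add(s_b, p_mood * p_b)
    return list(outcomes.items())


def build_cognitive_mdp(
    profile: MindsetProfile,
    env: EnvironmentConfig,
    space: StateSpace = STATE_SPACE,
) -> tuple[TransitionModel, RewardModel]:
    """Compile a profile's subjective MDP over the full discrete state space.

    A virtual absorbing terminal state (index ``space.n_states``) is
    appended; STOP transitions into it and the transition carries the
    end-of-play reward. Every move, STOP included, pays the time cost.
    """
    n = space.n_states
    terminal_idx = n

    def transitions(s: int, a: int) -> list[tuple[int, float]]:
        if a == Action.STOP:
            return [(terminal_idx, 1.0)]
        state = GameState.from_tuple(space.decode(s))
        outs = subjective_transition(profile, state, Action(a), env)
        return [(space.encode(sp.as_tuple()), p) for sp, p in outs]

    def reward(s: int, a: int, sp: int) -> float:
        r = profile.time_cost
        if a == Action.STOP:
            r += terminal_reward(profile, GameState.from_tuple(space.decode(s)))
        return r

    def available(s: int):
        state = GameState.from_tuple(space.decode(s))
        return [int(a) for a in available_actions(state)]

    tm = TransitionModel(
        n_states=n + 1,
        n_actions=len(ACTIONS),
        transitions=transitions,
        terminal=lambda s: s == terminal_idx,
        available=lambda s: [] if s == terminal_idx else available(s),
    )
    return tm, RewardModel(reward=reward)
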