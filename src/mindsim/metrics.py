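"""Behavioral validity metrics and group statistics.

Four theory-driven criteria distinguish the mindsets in simulated play:

1. *Cultural learning* — how far the three formality beliefs moved from
   their initial values by the end of a game (all real-world movement is
   toward the true culture, so movement equals learning).
2. *Efficiency* — conversations per game and dialog turns per conversation.
3. *Persistence* — conversational quitting (leaving a conversation without
   water in fewer than 4 dialog turns) and game quitting (ending the game
   without water after fewer than 3 conversations).
4. *Responsiveness to feedback* — within a conversation, an incorrect
   formality later followed by at least two uses of the correct formality.

Score comparisons use Welch two-sided t-tests on per-player means;
proportion comparisons use 1-df Pearson chi-square tests pooled over all
conversations or games.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulation import PlayRecord
from .water_task import (
    Action,
    AgeClass,
    Culture,
    TRUE_CULTURE,
)
from . import water_task

__all__ = [
    "Conversation",
    "GroupComparison",
    "learning_score",
    "belief_movement",
    "segment_conversations",
    "quit_flags",
    "responsiveness",
    "npc_age_proportions",
    "welch_t",
    "chi_square_prop",
    "player_summaries",
    "compare_groups",
]


@dataclass
class Conversation:
    """One SELECT ... LEAVE/STOP/end span of a record."""

    age: AgeClass
    dialog_actions: list[Action]
    got_water: bool
    feedback_valences: list[str]

    @property
    def n_turns(self) -> int:
        """Dialog turns: greet/ask actions only (navigation excluded)."""
        return len(self.dialog_actions)


@dataclass
class GroupComparison:
    """A two-group test result: Welch t (means) or Pearson chi-square (counts)."""

    metric: str
    kind: str  # "welch_t" | "chi_square"
    group_a: str
    group_b: str
    statistic: float
    df: float
    p_value: float
    effect_size: float | None = None  # Cohen's d for welch_t
    mean_a: float | None = None
    mean_b: float | None = None
    sd_a: float | None = None
    sd_b: float | None = None
    counts: tuple | None = None  # (successes_a, total_a, successes_b, total_b)

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "kind": self.kind,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sd_a": self.sd_a,
            "sd_b": self.sd_b,
            "counts": self.counts,
        }


def belief_movement(initial, final) -> int:
    """Sum over the three beliefs of |final - initial| (order: old, mid, young)."""
    return int(sum(abs(int(f) - int(i)) for i, f in zip(initial, final)))


def learning_score(record: PlayRecord) -> int:
    """Total belief movement from a record's first to last state.

    Real-world updates only ever move beliefs toward the true culture, so
    this equals the amount of cultural learning. Maximum 7 from the fixed
    initials (0 + 3 + 4) and 6 from the malleable initials (2 + 2 + 2).
    """
    return belief_movement(record.initial_state.beliefs, record.final_state.beliefs)


def segment_conversations(record: PlayRecord) -> list[Conversation]:
    """Split a record into conversations.

    Each SELECT opens a conversation with that NPC age class; LEAVE, STOP,
    or the end of the record closes it. Dialog turns are the greet/ask
    actions inside the span.
    """
    conversations: list[Conversation] = []
    current: Conversation | None = None
    for step in record.steps:
        a = step.action
        if a in water_task.SELECT_ACTIONS:
            if current is not None:
                raise ValueError("SELECT inside an open conversation")
            current = Conversation(
                age=step.state_after.npc_age,
                dialog_actions=[],
                got_water=False,
                feedback_valences=[],
            )
        elif a in water_task.DIALOG_ACTIONS:
            if current is None:
                raise ValueError("dialog action outside a conversation")
            current.dialog_actions.append(a)
            current.feedback_valences.append(step.feedback.valence.value)
            if step.state_after.got_water and not step.state_before.got_water:
                current.got_water = True
        elif a in (Action.LEAVE, Action.STOP):
            if current is not None:
                conversations.append(current)
                current = None
    if current is not None:  # record hit the step cap mid-conversation
        conversations.append(current)
    return conversations


def quit_flags(record: PlayRecord) -> tuple[list[bool], bool]:
    """(per-conversation quit flags, game quit flag).

    Conversational quit: the conversation ended without the water being
    revealed in it and had fewer than 4 dialog turns. Game quit: the record
    ended without water after fewer than 3 conversations.
    """
    convs = segment_conversations(record)
    conv_quits = [(not c.got_water) and c.n_turns < 4 for c in convs]
    game_quit = record.final_state.got_water == 0 and len(convs) < 3
    return conv_quits, game_quit


def _is_formal(action: Action) -> bool:
    return action in water_task.FORMAL_ACTIONS


def responsiveness(conversation: Conversation, culture: Culture = TRUE_CULTURE) -> str:
    """Classify a conversation as responsive / unresponsive / not_applicable.

    Correctness is judged against the true culture for the conversation's
    age class. Conversations with no incorrect-formality use are
    not_applicable; responsive means some incorrect use is followed, later
    in the conversation, by at least two correct-formality uses.
    """
    if conversation.age == AgeClass.NONE:
        raise ValueError("conversation has no NPC age class")
    wants_formal = culture.likes_formal[conversation.age]
    correct = [_is_formal(a) == wants_formal for a in conversation.dialog_actions]
    if all(correct):
        return "not_applicable"
    for i, ok in enumerate(correct):
        if not ok and sum(correct[i + 1 :]) >= 2:
            return "responsive"
    return "unresponsive"


def npc_age_proportions(records: Iterable[PlayRecord]) -> dict[AgeClass, float]:
    """Proportion of conversations opened with each age class; sums to 1."""
    counts = {AgeClass.YOUNG: 0, AgeClass.MID: 0, AgeClass.OLD: 0}
    for r in records:
        for c in segment_conversations(r):
            counts[c.age] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no conversations in the given records")
    return {age: n / total for age, n in counts.items()}


def welch_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    metric: str = "",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Welch two-sided t-test with Welch-Satterthwaite df and pooled-SD Cohen's d.

    d = (mean_a - mean_b) / sqrt((var_a + var_b) / 2), using n-1 variances.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return GroupComparison(
                metric=metric, kind="welch_t", group_a=labels[0], group_b=labels[1],
                statistic=0.0, df=float(a.size + b.size - 2), p_value=1.0,
                effect_size=0.0, mean_a=float(a.mean()), mean_b=float(b.mean()),
                sd_a=0.0, sd_b=0.0,
            )
        raise ValueError("both groups have zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa2, sb2 = va / a.size, vb / b.size
    df = (sa2 + sb2) ** 2 / (sa2**2 / (a.size - 1) + sb2**2 / (b.size - 1))
    d = (a.mean() - b.mean()) / np.sqrt((va + vb) / 2)
    return GroupComparison(
        metric=metric,
        kind="welch_t",
        group_a=labels[0],
        group_b=labels[1],
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        effect_size=float(d),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(np.sqrt(va)),
        sd_b=float(np.sqrt(vb)),
    )


def chi_square_prop(
    successes_a: int,
    total_a: int,
    successes_b: int,
    total_b: int,
    metric: str = "",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """1-df Pearson chi-square on the 2x2 table, no continuity correction."""
    if total_a < 1 or total_b < 1:
        raise ValueError("totals must be >= 1")
    if not (0 <= successes_a <= total_a and 0 <= successes_b <= total_b):
        raise ValueError("successes must lie in [0, total]")
    table = np.array(
        [
            [successes_a, total_a - successes_a],
            [successes_b, total_b - successes_b],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a margin of the 2x2 table is zero")
    res = stats.chi2_contingency(table, correction=False)
    return GroupComparison(
        metric=metric,
        kind="chi_square",
        group_a=labels[0],
        group_b=labels[1],
        statistic=float(res.statistic),
        df=1.0,
        p_value=float(res.pvalue),
        mean_a=successes_a / total_a,
        mean_b=successes_b / total_b,
        counts=(successes_a, total_a, successes_b, total_b),
    )


# ---------------------------------------------------------------------------
# Aggregation


def player_summaries(records: Iterable[PlayRecord]) -> pd.DataFrame:
    """Per-player metric means, aggregated over each player's runs.

    Returns one row per player with mean learning, mean conversations per
    game, mean dialog turns per conversation (total turns / total
    conversations over the player's games), quit and responsiveness counts,
    and NPC-age selection counts.
    """
    rows: dict[str, dict] = {}
    for r in records:
        row = rows.setdefault(
            r.player_id,
            {
                "player_id": r.player_id,
                "mindset": r.mindset,
                "beta": r.beta,
                "n_games": 0,
                "n_actions": 0,
                "learning_sum": 0,
                "n_conversations": 0,
                "n_turns": 0,
                "conv_quits": 0,
                "game_quits": 0,
                "responsive": 0,
                "unresponsive": 0,
                "water_games": 0,
                "select_young": 0,
                "select_mid": 0,
                "select_old": 0,
            },
        )
        convs = segment_conversations(r)
        conv_quits, game_quit = quit_flags(r)
        row["n_games"] += 1
        row["n_actions"] += len(r.steps)
        row["learning_sum"] += learning_score(r)
        row["n_conversations"] += len(convs)
        row["n_turns"] += sum(c.n_turns for c in convs)
        row["conv_quits"] += sum(conv_quits)
        row["game_quits"] += int(game_quit)
        row["water_games"] += int(r.final_state.got_water)
        for c in convs:
            verdict = responsiveness(c)
            if verdict == "responsive":
                row["responsive"] += 1
            elif verdict == "unresponsive":
                row["unresponsive"] += 1
            row[f"select_{c.age.name.lower()}"] += 1
    df = pd.DataFrame(sorted(rows.values(), key=lambda d: d["player_id"]))
    df["mean_learning"] = df["learning_sum"] / df["n_games"]
    df["mean_actions"] = df["n_actions"] / df["n_games"]
    df["mean_conversations"] = df["n_conversations"] / df["n_games"]
    with np.errstate(invalid="ignore"):
        df["mean_turns_per_conversation"] = np.where(
            df["n_conversations"] > 0, df["n_turns"] / df["n_conversations"], np.nan
        )
    return df


def compare_groups(summaries: pd.DataFrame) -> list[GroupComparison]:
    """The full fixed-vs-malleable comparison battery.

    t-tests run on per-player means (malleable listed first, as group_a);
    chi-square tests pool counts over all conversations or games.
    """
    mall = summaries[summaries["mindset"] == "malleable"]
    fix = summaries[summaries["mindset"] == "fixed"]
    labels = ("malleable", "fixed")
    out = [
        welch_t(mall["mean_learning"], fix["mean_learning"],
                metric="mean_learning", labels=labels),
        welch_t(mall["mean_conversations"], fix["mean_conversations"],
                metric="mean_conversations_per_game", labels=labels),
        welch_t(mall["mean_turns_per_conversation"].dropna(),
                fix["mean_turns_per_conversation"].dropna(),
                metric="mean_turns_per_conversation", labels=labels),
        welch_t(mall["mean_actions"], fix["mean_actions"],
                metric="mean_actions_per_game", labels=labels),
    ]

    def totals(df: pd.DataFrame, col: str) -> int:
        return int(df[col].sum())

    def safe_chi(sa, ta, sb, tb, metric):
        """Chi-square row, degrading to NaN when a margin is degenerate
        (possible on very small cohorts); proportions still reported."""
        try:
            return chi_square_prop(sa, ta, sb, tb, metric=metric, labels=labels)
        except ValueError:
            return GroupComparison(
                metric=metric, kind="chi_square", group_a=labels[0],
                group_b=labels[1], statistic=float("nan"), df=1.0,
                p_value=float("nan"),
                mean_a=sa / ta if ta else float("nan"),
                mean_b=sb / tb if tb else float("nan"),
                counts=(sa, ta, sb, tb),
            )

    out.append(
        safe_chi(
            totals(mall, "conv_quits"), totals(mall, "n_conversations"),
            totals(fix, "conv_quits"), totals(fix, "n_conversations"),
            "conversational_quitting",
        )
    )
    out.append(
        safe_chi(
            totals(mall, "game_quits"), totals(mall, "n_games"),
            totals(fix, "game_quits"), totals(fix, "n_games"),
            "game_quitting",
        )
    )
    out.append(
        safe_chi(
            totals(mall, "responsive"), totals(mall, "n_conversations"),
            totals(fix, "responsive"), totals(fix, "n_conversations"),
            "responsiveness_all_conversations",
        )
    )
    out.append(
        safe_chi(
            totals(mall, "responsive"),
            totals(mall, "responsive") + totals(mall, "unresponsive"),
            totals(fix, "responsive"),
            totals(fix, "responsive") + totals(fix, "unresponsive"),
            "responsiveness_given_incorrect",
        )
    )
    # NPC age selection: 2x3 contingency over all conversations.
    table = np.array(
        [
            [totals(mall, "select_young"), totals(mall, "select_mid"),
             totals(mall, "select_old")],
            [totals(fix, "select_young"), totals(fix, "select_mid"),
             totals(fix, "select_old")],
        ]
    )
    res = stats.chi2_contingency(table, correction=False)
    out.append(
        GroupComparison(
            metric="npc_age_selection",
            kind="chi_square",
            group_a="malleable",
            group_b="fixed",
            statistic=float(res.statistic),
            df=float(res.dof),
            p_value=float(res.pvalue),
            counts=tuple(table.ravel()),
        )
    )
    return out
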