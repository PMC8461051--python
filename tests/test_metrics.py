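"""Tests for the behavioral metrics and the statistical comparison layer."""

import numpy as np
import pytest

from mindsim.metrics import (
    belief_movement,
    chi_square_prop,
    learning_score,
    npc_age_proportions,
    player_summaries,
    quit_flags,
    responsiveness,
    segment_conversations,
    welch_t,
    Conversation,
)
from mindsim.profiles import FIXED_PROFILE, MALLEABLE_PROFILE
from mindsim.simulation import PlayRecord, Step
from mindsim.water_task import (
    Action,
    AgeClass,
    Feedback,
    GameState,
    TRUE_CULTURE,
    Valence,
    initial_situation,
)

NO_FB = Feedback(valence=Valence.NONE)


def _make_record(actions, mindset="fixed", final_beliefs=None, got_water=0):
    """Build a minimal consistent record walking the given action sequence.

    Feedback/belief details are irrelevant to segmentation metrics; states
    only track conversation structure plus optional final beliefs/water.
    """
    profile = FIXED_PROFILE if mindset == "fixed" else MALLEABLE_PROFILE
    state = profile.initial_state()
    steps = []
    age_for = {
        Action.SELECT_NPC_YOUNG: AgeClass.YOUNG,
        Action.SELECT_NPC_MID: AgeClass.MID,
        Action.SELECT_NPC_OLD: AgeClass.OLD,
    }
    import dataclasses

    for a in actions:
        if a in age_for:
            new = dataclasses.replace(state, in_conversation=1, npc_age=age_for[a])
            fb = NO_FB
        elif a in (Action.LEAVE, Action.STOP):
            if a == Action.LEAVE:
                new = dataclasses.replace(
                    state, in_conversation=0, npc_age=AgeClass.NONE,
                    greeted=0, asked=0, npc_happy=0,
                )
            else:
                new = state
            fb = NO_FB
        else:
            flag = (
                {"greeted": 1}
                if a in (Action.GREET_FORMAL, Action.GREET_INFORMAL)
                else {"asked": 1}
            )
            new = dataclasses.replace(state, **flag)
            fb = Feedback(valence=Valence.POSITIVE, tag="nice_reply", age=state.npc_age)
        steps.append(Step(state, a, fb, new))
        state = new
    if final_beliefs is not None or got_water:
        final = steps[-1].state_after
        beliefs = final_beliefs if final_beliefs is not None else final.beliefs
        patched = dataclasses.replace(
            final,
            old_likes_formal=beliefs[0],
            mid_likes_formal=beliefs[1],
            young_likes_formal=beliefs[2],
            got_water=got_water,
        )
        steps[-1] = dataclasses.replace(steps[-1], state_after=patched)
    return PlayRecord(
        player_id=f"{mindset}-test", mindset=mindset, beta=1.0, run_index=0,
        seed=0, steps=steps, end_reason="STOP" if actions[-1] == Action.STOP else "cap",
    )


# ---------------------------------------------------------------------------
# learning score


def test_learning_score_max_fixed():
    r = _make_record([Action.STOP], mindset="fixed",
                     final_beliefs=TRUE_CULTURE.correct_beliefs)
    assert learning_score(r) == 7  # 0 + 3 + 4


def test_learning_score_max_malleable():
    r = _make_record([Action.STOP], mindset="malleable",
                     final_beliefs=TRUE_CULTURE.correct_beliefs)
    assert learning_score(r) == 6  # 2 + 2 + 2


def test_learning_score_no_change_is_zero():
    r = _make_record([Action.STOP])
    assert learning_score(r) == 0


def test_learning_score_bounds_on_cohort(scaled_cohort):
    for r in scaled_cohort[::41]:
        score = learning_score(r)
        assert 0 <= score <= (7 if r.mindset == "fixed" else 6)


# ---------------------------------------------------------------------------
# segmentation


def test_segment_conversations_example():
    r = _make_record([
        Action.SELECT_NPC_OLD, Action.GREET_FORMAL, Action.ASK_FORMAL, Action.LEAVE,
        Action.SELECT_NPC_MID, Action.GREET_INFORMAL, Action.STOP,
    ])
    convs = segment_conversations(r)
    assert [c.n_turns for c in convs] == [2, 1]
    assert [c.age for c in convs] == [AgeClass.OLD, AgeClass.MID]


def test_segment_no_select_means_no_conversations():
    r = _make_record([Action.STOP])
    assert segment_conversations(r) == []


def test_conversation_count_equals_select_count(scaled_cohort):
    for r in scaled_cohort[::53]:
        n_selects = sum(
            1 for a in r.actions
            if a in (Action.SELECT_NPC_YOUNG, Action.SELECT_NPC_MID,
                     Action.SELECT_NPC_OLD)
        )
        assert len(segment_conversations(r)) == n_selects


# ---------------------------------------------------------------------------
# quitting


def test_conversational_quit_short_conversation_without_water():
    r = _make_record([
        Action.SELECT_NPC_OLD, Action.GREET_FORMAL, Action.ASK_FORMAL,
        Action.ASK_FORMAL, Action.LEAVE, Action.STOP,
    ])
    conv_quits, game_quit = quit_flags(r)
    assert conv_quits == [True]  # 3 dialog turns < 4, no water
    assert game_quit is True  # 1 conversation < 3, no water


def test_game_quit_requires_strictly_fewer_than_three_conversations():
    actions = []
    for _ in range(3):
        actions += [Action.SELECT_NPC_OLD, Action.GREET_FORMAL, Action.LEAVE]
    actions += [Action.STOP]
    r = _make_record(actions)
    _, game_quit = quit_flags(r)
    assert game_quit is False


def test_no_game_quit_with_water():
    r = _make_record(
        [Action.SELECT_NPC_OLD, Action.GREET_FORMAL, Action.ASK_FORMAL,
         Action.LEAVE, Action.STOP],
        got_water=1,
    )
    # water obtained in the final ask: mark the transition accordingly
    conv_quits, game_quit = quit_flags(r)
    assert game_quit is False


# ---------------------------------------------------------------------------
# responsiveness


def _conv(age, actions):
    return Conversation(age=age, dialog_actions=list(actions), got_water=False,
                        feedback_valences=["negative"] * len(actions))


def test_responsive_incorrect_then_two_correct():
    c = _conv(AgeClass.OLD, [Action.GREET_INFORMAL, Action.ASK_FORMAL,
                             Action.ASK_FORMAL])
    assert responsiveness(c) == "responsive"


def test_unresponsive_with_single_correction():
    c = _conv(AgeClass.OLD, [Action.GREET_INFORMAL, Action.ASK_FORMAL])
    assert responsiveness(c) == "unresponsive"


def test_not_applicable_without_incorrect_use():
    c = _conv(AgeClass.OLD, [Action.GREET_FORMAL, Action.ASK_FORMAL])
    assert responsiveness(c) == "not_applicable"


def test_responsiveness_respects_age_class_norm():
    # MID prefers informal: informal actions are the correct ones
    c = _conv(AgeClass.MID, [Action.GREET_FORMAL, Action.ASK_INFORMAL,
                             Action.ASK_INFORMAL])
    assert responsiveness(c) == "responsive"


def test_responsiveness_denominator_partition(scaled_cohort):
    """responsive + unresponsive together count exactly the conversations
    containing at least one incorrect-formality action."""
    from mindsim import water_task

    n_with_incorrect = 0
    n_resp = n_unresp = 0
    for r in scaled_cohort[::29]:
        for c in segment_conversations(r):
            wants_formal = TRUE_CULTURE.likes_formal[c.age]
            incorrect = any(
                (a in water_task.FORMAL_ACTIONS) != wants_formal
                for a in c.dialog_actions
            )
            n_with_incorrect += int(incorrect)
            verdict = responsiveness(c)
            n_resp += verdict == "responsive"
            n_unresp += verdict == "unresponsive"
    assert n_resp + n_unresp == n_with_incorrect


# ---------------------------------------------------------------------------
# proportions


def test_npc_age_proportions_counting():
    r = _make_record([
        Action.SELECT_NPC_YOUNG, Action.LEAVE,
        Action.SELECT_NPC_YOUNG, Action.LEAVE,
        Action.SELECT_NPC_MID, Action.LEAVE,
        Action.SELECT_NPC_OLD, Action.STOP,
    ])
    props = npc_age_proportions([r])
    assert props[AgeClass.YOUNG] == pytest.approx(0.5)
    assert props[AgeClass.MID] == pytest.approx(0.25)
    assert props[AgeClass.OLD] == pytest.approx(0.25)
    assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)


def test_npc_age_proportions_requires_conversations():
    r = _make_record([Action.STOP])
    with pytest.raises(ValueError):
        npc_age_proportions([r])


# ---------------------------------------------------------------------------
# statistics


def test_welch_identical_groups():
    c = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert c.statistic == pytest.approx(0.0)
    assert c.p_value == pytest.approx(1.0)
    assert c.effect_size == pytest.approx(0.0)


def test_welch_reference_values():
    c = welch_t([1, 2, 3], [2, 4, 6])
    assert c.statistic == pytest.approx(-1.549, abs=1e-3)
    assert c.df == pytest.approx(2.94, abs=0.01)


def test_welch_cohens_d_antisymmetric():
    a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 9.0]
    assert welch_t(a, b).effect_size == pytest.approx(-welch_t(b, a).effect_size)


def test_welch_errors():
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        welch_t([1.0, 1.0], [2.0, 2.0])


def test_chi_square_equal_proportions():
    c = chi_square_prop(30, 100, 30, 100)
    assert c.statistic == pytest.approx(0.0)
    assert c.p_value == pytest.approx(1.0)


def test_chi_square_hand_computed():
    # n(ad - bc)^2 / (r1 r2 c1 c2) = 200 * 2000^2 / (100*100*40*160) = 12.5
    c = chi_square_prop(30, 100, 10, 100)
    assert c.statistic == pytest.approx(12.5)
    assert c.df == 1.0


def test_chi_square_symmetric_in_groups():
    a = chi_square_prop(12, 60, 30, 90)
    b = chi_square_prop(30, 90, 12, 60)
    assert a.statistic == pytest.approx(b.statistic)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError):
        chi_square_prop(0, 10, 0, 10)


# ---------------------------------------------------------------------------
# aggregation


def test_player_summaries_aggregate_all_runs(scaled_cohort):
    df = player_summaries(scaled_cohort)
    assert len(df) == 100
    assert (df["n_games"] == 20).all()
    assert set(df["mindset"]) == {"fixed", "malleable"}
    # mean learning within theoretical bounds
    fixed = df[df["mindset"] == "fixed"]
    mall = df[df["mindset"] == "malleable"]
    assert fixed["mean_learning"].between(0, 7).all()
    assert mall["mean_learning"].between(0, 6).all()
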