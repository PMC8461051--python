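"""Unit and property tests for the generic MDP machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mindsim.mdp import (
    QIterationError,
    RewardModel,
    StateSpace,
    TransitionModel,
    q_iteration,
    sample_action,
    sequence_log_likelihood,
    softmax_action_probs,
)

from _toys import layered_toy, oracle_q


# ---------------------------------------------------------------------------
# StateSpace


def test_state_space_counts_and_roundtrip():
    space = StateSpace((("a", -2, 2), ("b", 0, 1), ("c", 0, 3)))
    assert space.n_states == 5 * 2 * 4
    for i in range(space.n_states):
        assert space.encode(space.decode(i)) == i
    assert space.decode(0) == (-2, 0, 0)


def test_state_space_rejects_out_of_range():
    space = StateSpace((("a", 0, 1),))
    with pytest.raises(ValueError):
        space.encode((2,))
    with pytest.raises(ValueError):
        space.decode(5)
    with pytest.raises(ValueError):
        StateSpace((("bad", 3, 1),))


# ---------------------------------------------------------------------------
# softmax


def test_softmax_uniform_at_beta_zero():
    p = softmax_action_probs(np.array([3.0, -1.0, 0.5]), beta=0.0)
    assert np.allclose(p, 1 / 3)


def test_softmax_closed_form():
    p = softmax_action_probs(np.array([1.0, 0.0]), beta=1.0)
    assert p == pytest.approx([0.7311, 0.2689], abs=1e-4)


def test_softmax_concentrates_at_large_beta():
    p = softmax_action_probs(np.array([1.0, 0.0]), beta=50.0)
    assert p[0] > 0.999


def test_softmax_mapping_interface_and_errors():
    p = softmax_action_probs({"x": 1.0, "y": 0.0}, beta=1.0)
    assert p["x"] == pytest.approx(0.7311, abs=1e-4)
    with pytest.raises(ValueError):
        softmax_action_probs(np.array([]), beta=1.0)
    with pytest.raises(ValueError):
        softmax_action_probs(np.array([1.0]), beta=-0.5)


@settings(deadline=None, max_examples=50)
@given(
    qs=st.lists(st.floats(-10, 10), min_size=1, max_size=6),
    shift=st.floats(-100, 100),
    beta=st.floats(0, 20),
)
def test_softmax_shift_invariance(qs, shift, beta):
    """Adding a constant to every Q value leaves the distribution unchanged.

    Q spans are kept within beta * range < 700 so no probability underflows
    to exactly zero (below that the softmax is positive by construction).
    """
    q = np.array(qs)
    p1 = softmax_action_probs(q, beta)
    p2 = softmax_action_probs(q + shift, beta)
    assert np.allclose(p1, p2, atol=1e-9)
    assert p1.sum() == pytest.approx(1.0, abs=1e-9)
    assert (p1 > 0).all()


def test_softmax_overflow_safe():
    p = softmax_action_probs(np.array([1000.0, 0.0]), beta=10.0)
    assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# sample_action


def test_sample_action_degenerate_and_deterministic():
    rng = np.random.default_rng(0)
    assert sample_action({"a": 1.0, "b": 0.0}, rng) == "a"
    d = ([0, 1, 2], [0.2, 0.3, 0.5])
    draws1 = [sample_action(d, np.random.default_rng(7)) for _ in range(20)]
    draws2 = [sample_action(d, np.random.default_rng(7)) for _ in range(20)]
    # a fresh generator with the same seed reproduces the same draw each time
    assert draws1 == draws2


def test_sample_action_frequencies_within_binomial_bound():
    rng = np.random.default_rng(424242)
    n = 10_000
    draws = [sample_action(([0, 1], [0.5, 0.5]), rng) for _ in range(n)]
    freq = sum(draws) / n
    sigma = 0.5 / np.sqrt(n)
    assert abs(freq - 0.5) < 3 * sigma


def test_sample_action_rejects_invalid():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        sample_action(([0, 1], [0.7, 0.7]), rng)
    with pytest.raises(ValueError):
        sample_action(([], []), rng)


# ---------------------------------------------------------------------------
# q_iteration


def _chain():
    """s0 -a-> s1 (r=0), s1 -a-> terminal (r=5)."""
    tm = TransitionModel(
        n_states=3,
        n_actions=1,
        transitions=lambda s, a: [(s + 1, 1.0)],
        terminal=lambda s: s == 2,
        available=lambda s: [] if s == 2 else [0],
    )
    rm = RewardModel(reward=lambda s, a, sp: 5.0 if s == 1 else 0.0)
    return tm, rm


def test_two_state_chain_backsubstitution():
    tm, rm = _chain()
    q = q_iteration(tm, rm, gamma=0.9, beta=100.0, tol=1e-10)
    assert q.values[1, 0] == pytest.approx(5.0, abs=1e-8)
    assert q.values[0, 0] == pytest.approx(4.5, abs=1e-8)


def test_gamma_zero_gives_expected_immediate_reward():
    tm, rm = layered_toy(np.random.default_rng(11))
    q = q_iteration(tm, rm, gamma=0.0, beta=3.0, tol=1e-12)
    for s in range(tm.n_states):
        if tm.terminal(s):
            continue
        for a in tm.available(s):
            expected = sum(p * rm(s, a, sp) for sp, p in tm.transitions(s, a))
            assert q.values[s, a] == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("seed", [1, 2, 3, 4])
@pytest.mark.parametrize("beta", [0.0, 1.0, 10.0])
def test_q_iteration_matches_brute_force_oracle(seed, beta):
    """Iterative solution equals direct recursion on random 4-layer DAGs."""
    rng = np.random.default_rng(seed)
    tm, rm = layered_toy(rng)
    gamma = 0.9
    q = q_iteration(tm, rm, gamma=gamma, beta=beta, tol=1e-12)
    expected = oracle_q(tm, rm, gamma=gamma, beta=beta)
    for (s, a), v in expected.items():
        assert q.values[s, a] == pytest.approx(v, abs=1e-6)


def test_greedy_backup_is_value_iteration():
    tm, rm = layered_toy(np.random.default_rng(12))
    q_soft = q_iteration(tm, rm, gamma=0.9, beta=1e6, tol=1e-12)
    q_greedy = q_iteration(tm, rm, gamma=0.9, beta=1.0, tol=1e-12, backup="greedy")
    # softmax backup at huge beta converges to the greedy fixed point
    mask = q_soft.available
    assert np.allclose(q_soft.values[mask], q_greedy.values[mask], atol=1e-6)


def test_q_iteration_rejects_bad_arguments():
    tm, rm = _chain()
    with pytest.raises(ValueError):
        q_iteration(tm, rm, gamma=1.0)
    with pytest.raises(ValueError):
        q_iteration(tm, rm, gamma=0.5, tol=0.0)
    with pytest.raises(ValueError):
        q_iteration(tm, rm, backup="fancy")


def test_q_iteration_nonconvergence_reports_residual():
    # self-loop with reward 1 and gamma->1-ish cannot reach tol in 3 iterations
    tm = TransitionModel(
        n_states=1,
        n_actions=1,
        transitions=lambda s, a: [(0, 1.0)],
        terminal=lambda s: False,
        available=lambda s: [0],
    )
    rm = RewardModel(reward=lambda s, a, sp: 1.0)
    with pytest.raises(QIterationError) as err:
        q_iteration(tm, rm, gamma=0.99, beta=1.0, tol=1e-12, max_iter=3)
    assert err.value.residual > 0
    assert err.value.iterations == 3


# ---------------------------------------------------------------------------
# sequence log likelihood


def test_sequence_log_likelihood_single_step_half():
    tm, rm = _chain()
    q = q_iteration(tm, rm, gamma=0.9, beta=1.0)
    # one action available => p = 1, log p = 0; use a two-action toy for 0.5
    tm2 = TransitionModel(
        n_states=2,
        n_actions=2,
        transitions=lambda s, a: [(1, 1.0)],
        terminal=lambda s: s == 1,
        available=lambda s: [] if s == 1 else [0, 1],
    )
    rm2 = RewardModel(reward=lambda s, a, sp: 0.0)
    q2 = q_iteration(tm2, rm2, gamma=0.9, beta=1.0)
    ll = sequence_log_likelihood([(0, 0)], q2, beta=2.0)
    assert ll == pytest.approx(np.log(0.5), abs=1e-9)
    assert sequence_log_likelihood([], q2, beta=2.0) == 0.0


def test_sequence_log_likelihood_unavailable_action_is_minus_inf():
    tm, rm = _chain()
    q = q_iteration(tm, rm, gamma=0.9, beta=1.0)
    assert sequence_log_likelihood([(0, 0), (1, 0)], q, 1.0) == pytest.approx(0.0)
    assert np.isneginf(sequence_log_likelihood([(0, 0), (2, 0)], q, 1.0))


def test_sequence_log_likelihood_continuous_in_beta():
    tm, rm = layered_toy(np.random.default_rng(13))
    q = q_iteration(tm, rm, gamma=0.9, beta=2.0)
    pairs = [(0, 0), (3, 1), (7, 0)]
    grid = np.exp(np.linspace(-3, 3, 61))
    lls = [sequence_log_likelihood(pairs, q, b) for b in grid]
    assert np.isfinite(lls).all()
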