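"""Generic tabular-MDP machinery.

State spaces are finite products of integer-ranged variables. Q values are
solved by fixed-point iteration on the Bellman-style recursion

    Q(s, a) = sum_s' p(s'|s, a) * ( r(s, a, s') + gamma * V(s') )

where the future value ``V(s') = sum_a' pi(a'|s') Q(s', a')`` is taken under
the softmax (Boltzmann) policy ``pi(a|s) ∝ exp(beta * Q(s, a))`` consistent
with the Q values being solved ("softmax" backup), or under the greedy policy
``V(s') = max_a' Q(s', a')`` ("greedy" backup). The softmax backup is the
literal reading of the recursion with a noisy actor; as beta → ∞ it recovers
the greedy case.

Everything here is agnostic of the water task; the task modules compile
their dynamics into :class:`TransitionModel` / :class:`RewardModel` pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StateSpace",
    "TransitionModel",
    "RewardModel",
    "QTable",
    "Policy",
    "QIterationError",
    "q_iteration",
    "softmax_action_probs",
    "sample_action",
    "sequence_log_likelihood",
    "record_log_likelihood",
]


@dataclass(frozen=True)
class StateSpace:
    """Ordered product of integer-ranged variables with a dense index map.

    ``variables`` is a tuple of ``(name, lo, hi)`` with inclusive bounds.
    States are tuples of ints in variable order; ``encode``/``decode`` form a
    bijection with ``range(n_states)`` (mixed-radix, first variable most
    significant).
    """

    variables: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for name, lo, hi in self.variables:
            if lo > hi:
                raise ValueError(f"variable {name!r} has min {lo} > max {hi}")

    @property
    def n_states(self) -> int:
        n = 1
        for _, lo, hi in self.variables:
            n *= hi - lo + 1
        return n

    def encode(self, state: Sequence[int]) -> int:
        if len(state) != len(self.variables):
            raise ValueError("state length does not match variable count")
        idx = 0
        for value, (name, lo, hi) in zip(state, self.variables):
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
            idx = idx * (hi - lo + 1) + (value - lo)
        return idx

    def decode(self, idx: int) -> tuple[int, ...]:
        if not 0 <= idx < self.n_states:
            raise ValueError(f"state index {idx} outside [0, {self.n_states})")
        out = []
        for _, lo, hi in reversed(self.variables):
            size = hi - lo + 1
            idx, rem = divmod(idx, size)
            out.append(rem + lo)
        return tuple(reversed(out))

    def states(self) -> Iterable[tuple[int, ...]]:
        for i in range(self.n_states):
            yield self.decode(i)


@dataclass(frozen=True)
class TransitionModel:
    """Dynamics over integer state indices.

    ``transitions(s, a)`` returns ``[(s', p), ...]`` with probabilities
    summing to 1 for every non-terminal state and available action.
    ``available(s)`` lists the action indices available in ``s`` (empty for
    terminal states). ``terminal(s)`` marks absorbing end states, which carry
    no outgoing transitions and contribute zero future value.
    """

    n_states: int
    n_actions: int
    transitions: Callable[[int, int], list[tuple[int, float]]]
    terminal: Callable[[int], bool]
    available: Callable[[int], Sequence[int]]


@dataclass(frozen=True)
class RewardModel:
    """Immediate reward ``r(s, a, s')``; costs are negative."""

    reward: Callable[[int, int, int], float]

    def __call__(self, s: int, a: int, sp: int) -> float:
        return self.reward(s, a, sp)


class QIterationError(RuntimeError):
    """Raised when Q iteration fails to converge; carries the last residual."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


@dataclass
class QTable:
    """Solved action values on a dense (state, action) grid.

    ``values[s, a]`` is NaN where action ``a`` is unavailable in state ``s``
    (including every action of a terminal state). ``space`` and
    ``action_names`` are optional annotations used when scoring play records.
    """

    values: np.ndarray
    available: np.ndarray
    gamma: float
    beta: float
    iterations: int
    residual: float
    backup: str = "softmax"
    space: StateSpace | None = None
    action_names: tuple[str, ...] | None = None
    residual_history: list[float] | None = None

    def q_row(self, state_idx: int) -> np.ndarray:
        return self.values[state_idx]

    def to_frame(self) -> pd.DataFrame:
        """Flat (state index, action, value) table for inspection/CSV export."""
        s_idx, a_idx = np.nonzero(self.available)
        names = (
            [self.action_names[a] for a in a_idx]
            if self.action_names is not None
            else a_idx
        )
        return pd.DataFrame(
            {"state": s_idx, "action": names, "q": self.values[s_idx, a_idx]}
        )


@dataclass(frozen=True)
class Policy:
    """Softmax action distribution derived from a QTable at noise level beta."""

    q: QTable
    beta: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    def action_probs(self, state_idx: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(action indices, probabilities)`` for a state."""
        avail = np.nonzero(self.q.available[state_idx])[0]
        if avail.size == 0:
            raise ValueError(f"state {state_idx} is terminal (no actions)")
        probs = softmax_action_probs(self.q.values[state_idx, avail], self.beta)
        return avail, probs


def softmax_action_probs(
    q_row: Mapping[object, float] | Sequence[float] | np.ndarray, beta: float
):
    """Boltzmann distribution ``p(a) ∝ exp(beta * Q(a))`` with max-shift.

    Accepts either a mapping ``action -> Q`` (returns a dict of the same
    keys) or an array of Q values (returns an array). ``beta = 0`` yields the
    uniform distribution; large beta concentrates on the argmax.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    if isinstance(q_row, Mapping):
        keys = list(q_row.keys())
        probs = softmax_action_probs(np.array([q_row[k] for k in keys], float), beta)
        return dict(zip(keys, probs))
    q = np.asarray(q_row, dtype=float)
    if q.size == 0:
        raise ValueError("empty action set")
    z = beta * q
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def sample_action(dist, rng: np.random.Generator):
    """Draw one action from a distribution.

    ``dist`` is either a dict ``action -> probability`` or a pair
    ``(actions, probabilities)``. Probabilities must be nonnegative and sum
    to 1 within 1e-9.
    """
    if isinstance(dist, Mapping):
        actions = list(dist.keys())
        probs = np.array([dist[a] for a in actions], float)
    else:
        actions, probs = dist
        actions = list(actions)
        probs = np.asarray(probs, dtype=float)
    if len(actions) == 0:
        raise ValueError("empty action set")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("invalid probability distribution")
    i = rng.choice(len(actions), p=probs / probs.sum())
    return actions[i]


# ---------------------------------------------------------------------------
# Q iteration


def _compile(tm: TransitionModel, rm: RewardModel):
    """Flatten callables into arrays for vectorized iteration."""
    pair_state, pair_action, ptr = [], [], [0]
    ent_next, ent_prob, ent_rew = [], [], []
    avail = np.zeros((tm.n_states, tm.n_actions), dtype=bool)
    for s in range(tm.n_states):
        if tm.terminal(s):
            continue
        for a in tm.available(s):
            outs = tm.transitions(s, a)
            total = sum(p for _, p in outs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"transition probabilities for (s={s}, a={a}) sum to {total}"
                )
            pair_state.append(s)
            pair_action.append(a)
            avail[s, a] = True
            for sp, p in outs:
                ent_next.append(sp)
                ent_prob.append(p)
                ent_rew.append(rm(s, a, sp))
            ptr.append(len(ent_next))
    return (
        np.array(pair_state, dtype=np.int64),
        np.array(pair_action, dtype=np.int64),
        np.array(ptr, dtype=np.int64),
        np.array(ent_next, dtype=np.int64),
        np.array(ent_prob, dtype=float),
        np.array(ent_rew, dtype=float),
        avail,
    )


def _state_values(q: np.ndarray, avail: np.ndarray, beta: float, backup: str):
    """V(s) under the softmax (or greedy) policy; 0 for terminal states."""
    masked = np.where(avail, q, -np.inf)
    has_action = avail.any(axis=1)
    if backup == "greedy":
        v = np.where(has_action, masked.max(axis=1), 0.0)
        return v
    m = np.where(has_action, masked.max(axis=1), 0.0)
    with np.errstate(invalid="ignore"):  # 0 * -inf on unavailable entries
        w = np.exp(beta * (masked - m[:, None]))
    w[~avail] = 0.0
    denom = w.sum(axis=1)
    denom[~has_action] = 1.0
    v = (w * np.where(avail, q, 0.0)).sum(axis=1) / denom
    return np.where(has_action, v, 0.0)


def q_iteration(
    transitions: TransitionModel,
    rewards: RewardModel,
    gamma: float = 0.98,
    beta: float = 10.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    backup: str = "softmax",
    space: StateSpace | None = None,
    action_names: Sequence[str] | None = None,
) -> QTable:
    """Solve Q values by fixed-point iteration.

    Parameters
    ----------
    gamma : discount in [0, 1).
    beta : noise level of the backup policy (ignored for ``backup="greedy"``).
    backup : ``"softmax"`` (policy-consistent values, the default) or
        ``"greedy"`` (standard value iteration).
    """
    if not 0 <= gamma < 1:
        raise ValueError("gamma must lie in [0, 1) (no terminal-reachability check)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if backup not in ("softmax", "greedy"):
        raise ValueError(f"unknown backup {backup!r}")
    ps, pa, ptr, ent_next, ent_prob, ent_rew, avail = _compile(transitions, rewards)
    seg = np.repeat(np.arange(len(ps)), np.diff(ptr))
    base = np.bincount(seg, weights=ent_prob * ent_rew, minlength=len(ps))
    q = np.zeros((transitions.n_states, transitions.n_actions))
    residual = np.inf
    history: list[float] = []
    for it in range(1, max_iter + 1):
        v = _state_values(q, avail, beta, backup)
        q_pairs = base + gamma * np.bincount(
            seg, weights=ent_prob * v[ent_next], minlength=len(ps)
        )
        residual = float(np.max(np.abs(q_pairs - q[ps, pa]))) if len(ps) else 0.0
        history.append(residual)
        q[ps, pa] = q_pairs
        if residual < tol:
            out = np.full_like(q, np.nan)
            out[avail] = q[avail]
            return QTable(
                values=out,
                available=avail,
                gamma=gamma,
                beta=beta,
                iterations=it,
                residual=residual,
                backup=backup,
                space=space,
                action_names=tuple(action_names) if action_names else None,
                residual_history=history,
            )
    raise QIterationError(
        f"Q iteration did not converge in {max_iter} iterations "
        f"(residual {residual:.3e})",
        residual=residual,
        iterations=max_iter,
    )


# ---------------------------------------------------------------------------
# Log likelihood of action sequences


def sequence_log_likelihood(
    pairs: Sequence[tuple[int, int]], q: QTable, beta: float
) -> float:
    """Sum of log softmax action probabilities over (state index, action) pairs.

    Only action probabilities enter; state-transition probabilities are not
    part of the likelihood. An action unavailable in its state under this
    model contributes -inf.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    total = 0.0
    for s, a in pairs:
        avail = np.nonzero(q.available[s])[0]
        if a not in avail:
            return -np.inf
        z = beta * q.values[s, avail]
        z -= z.max()
        logp = z[avail == a][0] - np.log(np.exp(z).sum())
        total += float(logp)
    return total


def record_log_likelihood(record, q: QTable, beta: float) -> float:
    """Log likelihood of a play record's action choices under (Q, beta).

    The record's states are encoded through ``q.space``; see
    :func:`sequence_log_likelihood` for the accounting.
    """
    if q.space is None:
        raise ValueError("QTable has no state space annotation")
    pairs = [
        (q.space.encode(step.state_before.as_tuple()), int(step.action))
        for step in record.steps
    ]
    return sequence_log_likelihood(pairs, q, beta)
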