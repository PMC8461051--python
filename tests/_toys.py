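"""Tiny randomized MDPs and an independent brute-force Q oracle.

The toys are layered DAGs (at most 4 steps to the terminal layer), so the
softmax-consistent Q values can be computed by direct recursion over all
action continuations — fully independent of the iterative solver.
"""

from __future__ import annotations

import numpy as np

from mindsim.mdp import RewardModel, TransitionModel


def layered_toy(rng: np.random.Generator, n_layers: int = 4, per_layer: int = 3,
                n_actions: int = 2):
    """Random layered MDP: every non-final state has all actions available;
    each (state, action) moves to a random distribution over the next layer
    with a random bounded reward. The final layer is terminal."""
    layers = [list(range(i * per_layer, (i + 1) * per_layer)) for i in range(n_layers)]
    n_states = n_layers * per_layer
    trans: dict[tuple[int, int], list[tuple[int, float]]] = {}
    rews: dict[tuple[int, int, int], float] = {}
    for li, layer in enumerate(layers[:-1]):
        for s in layer:
            for a in range(n_actions):
                probs = rng.dirichlet(np.ones(per_layer))
                outs = []
                for sp, p in zip(layers[li + 1], probs):
                    outs.append((sp, float(p)))
                    rews[(s, a, sp)] = float(rng.uniform(-1, 1))
                trans[(s, a)] = outs
    terminal_states = set(layers[-1])
    tm = TransitionModel(
        n_states=n_states,
        n_actions=n_actions,
        transitions=lambda s, a: trans[(s, a)],
        terminal=lambda s: s in terminal_states,
        available=lambda s: [] if s in terminal_states else list(range(n_actions)),
    )
    rm = RewardModel(reward=lambda s, a, sp: rews[(s, a, sp)])
    return tm, rm


def oracle_q(tm: TransitionModel, rm: RewardModel, gamma: float, beta: float):
    """Softmax-consistent Q by memoized recursion (acyclic environments only)."""
    memo_q: dict[tuple[int, int], float] = {}
    memo_v: dict[int, float] = {}

    def v(s: int) -> float:
        if tm.terminal(s):
            return 0.0
        if s not in memo_v:
            qs = np.array([q(s, a) for a in tm.available(s)])
            z = beta * qs
            z = z - z.max()
            w = np.exp(z)
            memo_v[s] = float((w / w.sum()) @ qs)
        return memo_v[s]

    def q(s: int, a: int) -> float:
        if (s, a) not in memo_q:
            memo_q[(s, a)] = sum(
                p * (rm(s, a, sp) + gamma * v(sp)) for sp, p in tm.transitions(s, a)
            )
        return memo_q[(s, a)]

    return {
        (s, a): q(s, a)
        for s in range(tm.n_states)
        if not tm.terminal(s)
        for a in tm.available(s)
    }
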