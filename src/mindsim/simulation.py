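"""Cohort simulation: seeded play records for paired fixed/malleable players.

Each simulated player is a (mindset, beta) pair. Strategic ability beta is
drawn once per player pair from a lognormal(0, 1) distribution and shared by
one fixed and one malleable player, giving directly comparable pairs. Every
player then plays ``runs_per_player`` independent games; each game's record
is reproducible in isolation from (profile, beta, env, seed), with the
per-record seed derived deterministically from the master seed.

Q values are solved once per profile (planning is a property of the
mindset's subjective model, not of the individual); beta enters only the
softmax with which actions are drawn during play.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mdp import Policy, QTable, q_iteration, softmax_action_probs
from .profiles import PROFILES, MindsetProfile, build_cognitive_mdp
from .water_task import (
    ACTIONS,
    Action,
    EnvironmentConfig,
    Feedback,
    GameState,
    STATE_SPACE,
    available_actions,
    real_world_step,
)

__all__ = [
    "SimulationConfig",
    "Step",
    "PlayRecord",
    "draw_betas",
    "solve_profile",
    "solve_all_profiles",
    "simulate_record",
    "replay_record",
    "simulate_cohort",
    "scaled_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort design. Defaults are the full study conditions
    (500 player pairs, 100 games each, beta ~ lognormal(0, 1))."""

    n_players_per_mindset: int = 500
    runs_per_player: int = 100
    master_seed: int = 20260101
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    gamma: float = 0.98
    planning_beta: float = 10.0
    backup: str = "softmax"
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.n_players_per_mindset < 1 or self.runs_per_player < 1:
            raise ValueError("cohort counts must be >= 1")


def scaled_config(master_seed: int = 20260101, **overrides) -> SimulationConfig:
    """Desk-scale cohort (50 player pairs x 20 runs) for tests and quick runs."""
    overrides.setdefault("n_players_per_mindset", 50)
    overrides.setdefault("runs_per_player", 20)
    return SimulationConfig(master_seed=master_seed, **overrides)


@dataclass(frozen=True)
class Step:
    state_before: GameState
    action: Action
    feedback: Feedback
    state_after: GameState


@dataclass
class PlayRecord:
    """One full game: the ordered (state, action, feedback, state') sequence.

    ``end_reason`` is "STOP" when the player drew the STOP action and "cap"
    when the episode hit the step cap.
    """

    player_id: str
    mindset: str
    beta: float
    run_index: int
    seed: int
    steps: list[Step]
    end_reason: str

    @property
    def initial_state(self) -> GameState:
        return self.steps[0].state_before

    @property
    def final_state(self) -> GameState:
        return self.steps[-1].state_after

    @property
    def actions(self) -> list[Action]:
        return [s.action for s in self.steps]

    def validate(self) -> None:
        if not self.steps:
            raise ValueError("empty record")
        for a, b in zip(self.steps, self.steps[1:]):
            if a.state_after != b.state_before:
                raise ValueError("record states do not chain")
        if self.end_reason == "STOP":
            if self.steps[-1].action != Action.STOP:
                raise ValueError("STOP-terminated record must end with STOP")
        elif self.end_reason != "cap":
            raise ValueError(f"unknown end_reason {self.end_reason!r}")


def draw_betas(n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent lognormal(0, 1) strategic-ability draws (median 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.lognormal(mean=0.0, sigma=1.0, size=n)


def solve_profile(
    profile: MindsetProfile, config: SimulationConfig | None = None
) -> QTable:
    """Build and solve one profile's subjective MDP."""
    config = config or SimulationConfig()
    tm, rm = build_cognitive_mdp(profile, config.environment)
    return q_iteration(
        tm,
        rm,
        gamma=config.gamma,
        beta=config.planning_beta,
        tol=config.tol,
        max_iter=config.max_iter,
        backup=config.backup,
        space=STATE_SPACE,
        action_names=tuple(a.name for a in ACTIONS),
    )


def solve_all_profiles(
    config: SimulationConfig | None = None,
    profiles: Mapping[str, MindsetProfile] | None = None,
) -> dict[str, QTable]:
    profiles = PROFILES if profiles is None else profiles
    return {label: solve_profile(p, config) for label, p in profiles.items()}


def record_seed(master_seed: int, mindset: str, player_index: int, run_index: int) -> int:
    """Deterministic per-record seed; any record is re-simulable in isolation."""
    mindset_code = {"fixed": 1, "malleable": 2}[mindset]
    ss = np.random.SeedSequence((master_seed, mindset_code, player_index, run_index))
    return int(ss.generate_state(1)[0])


def _action_distribution(q: QTable, state: GameState, beta: float):
    s_idx = STATE_SPACE.encode(state.as_tuple())
    acts = available_actions(state)
    q_row = q.values[s_idx, [int(a) for a in acts]]
    return acts, softmax_action_probs(q_row, beta)


def simulate_record(
    profile: MindsetProfile,
    q: QTable,
    beta: float,
    env: EnvironmentConfig,
    seed: int,
    player_id: str = "",
    run_index: int = 0,
) -> PlayRecord:
    """Play one seeded game.

    Two independent RNG streams are derived from the seed: one for action
    sampling and one for the environment, so a recorded action sequence can
    be replayed through the environment stream alone (see
    :func:`replay_record`).
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    if np.isnan(q.values[q.available]).any():
        raise ValueError("QTable contains NaN among available actions (unsolved?)")
    act_rng, env_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    )
    state = profile.initial_state()
    steps: list[Step] = []
    end_reason = "cap"
    for _ in range(env.max_steps):
        acts, probs = _action_distribution(q, state, beta)
        action = acts[act_rng.choice(len(acts), p=probs)]
        new_state, feedback = real_world_step(state, action, profile, env, env_rng)
        steps.append(Step(state, action, feedback, new_state))
        state = new_state
        if action == Action.STOP:
            end_reason = "STOP"
            break
    return PlayRecord(
        player_id=player_id or profile.label,
        mindset=profile.label,
        beta=float(beta),
        run_index=run_index,
        seed=int(seed),
        steps=steps,
        end_reason=end_reason,
    )


def replay_record(record: PlayRecord, env: EnvironmentConfig) -> list[GameState]:
    """Re-run a record's actions through the environment stream of its seed.

    Returns the reconstructed state sequence (initial state first); it must
    equal the recorded one.
    """
    profile = PROFILES[record.mindset]
    _, env_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(record.seed).spawn(2)
    )
    state = record.initial_state
    out = [state]
    for step in record.steps:
        state, _ = real_world_step(state, step.action, profile, env, env_rng)
        out.append(state)
    return out


def simulate_cohort(
    config: SimulationConfig,
    q_tables: Mapping[str, QTable] | None = None,
    profiles: Mapping[str, MindsetProfile] | None = None,
    progress: bool = False,
) -> list[PlayRecord]:
    """Simulate the full paired cohort.

    For each of ``n_players_per_mindset`` beta draws, one fixed and one
    malleable player (sharing beta) each play ``runs_per_player`` games.
    Returns ``2 * n * runs`` records.
    """
    profiles_map = PROFILES if profiles is None else profiles
    if q_tables is None:
        q_tables = solve_all_profiles(config, profiles_map)
    beta_rng = np.random.default_rng(
        np.random.SeedSequence((config.master_seed, 0xBE7A))
    )
    betas = draw_betas(config.n_players_per_mindset, beta_rng)
    players: Iterable = range(config.n_players_per_mindset)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            players = tqdm(players, desc="players")
        except ImportError:
            pass
    records: list[PlayRecord] = []
    for i in players:
        for label, profile in profiles_map.items():
            player_id = f"{label}-{i:04d}"
            for j in range(config.runs_per_player):
                seed = record_seed(config.master_seed, label, i, j)
                records.append(
                    simulate_record(
                        profile,
                        q_tables[label],
                        beta=float(betas[i]),
                        env=config.environment,
                        seed=seed,
                        player_id=player_id,
                        run_index=j,
                    )
                )
    return records
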