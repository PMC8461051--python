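"""Run configuration: strict YAML round-trip for all model/run parameters.

``load_config()`` with no argument returns the packaged defaults
(``data/default_config.yaml``). A user file is merged over the defaults;
unknown keys anywhere are rejected so typos cannot silently fall back to a
default.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .profiles import MindsetProfile
from .simulation import SimulationConfig
from .water_task import EnvironmentConfig

__all__ = ["RunConfig", "load_config", "default_config"]

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    version: int
    master_seed: int
    output_dir: str
    environment: EnvironmentConfig
    profiles: Mapping[str, MindsetProfile]
    simulation: SimulationConfig
    beta_grid: np.ndarray
    oracle_beta: bool

    def to_dict(self) -> dict:
        """Plain-dict form that round-trips through :func:`_from_dict`."""
        env = self.environment
        table = env.table
        return {
            "version": self.version,
            "master_seed": self.master_seed,
            "output_dir": self.output_dir,
            "environment": {
                "p_reveal_happy": env.p_reveal_happy,
                "p_reveal_unhappy": env.p_reveal_unhappy,
                "max_steps": env.max_steps,
            },
            "profiles": {
                label: {
                    "initial_beliefs": list(p.initial_beliefs),
                    "belief_reward_bands": list(p.belief_reward_bands),
                    "time_cost": p.time_cost,
                    "water_reward": p.water_reward,
                    "subjective_update": p.subjective_update,
                }
                for label, p in self.profiles.items()
            },
            "belief_update_table": {
                str(k): dict(v) for k, v in sorted(table.items())
            },
            "simulation": {
                "n_players_per_mindset": self.simulation.n_players_per_mindset,
                "runs_per_player": self.simulation.runs_per_player,
                "gamma": self.simulation.gamma,
                "planning_beta": self.simulation.planning_beta,
                "backup": self.simulation.backup,
                "tol": self.simulation.tol,
                "max_iter": self.simulation.max_iter,
            },
            "classification": {
                "log_beta_min": float(np.log(self.beta_grid[0])),
                "log_beta_max": float(np.log(self.beta_grid[-1])),
                "log_beta_step": float(
                    np.log(self.beta_grid[1]) - np.log(self.beta_grid[0])
                )
                if len(self.beta_grid) > 1
                else 0.125,
                "oracle_beta": self.oracle_beta,
            },
        }


def _check_keys(obj: dict, allowed: set[str], context: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")


def _from_dict(raw: dict) -> RunConfig:
    _check_keys(
        raw,
        {
            "version",
            "master_seed",
            "output_dir",
            "environment",
            "profiles",
            "belief_update_table",
            "simulation",
            "classification",
        },
        "top level",
    )
    if raw["version"] != _SCHEMA_VERSION:
        raise ValueError(
            f"unsupported config version {raw['version']!r} (expected {_SCHEMA_VERSION})"
        )
    env_raw = dict(raw["environment"])
    _check_keys(
        env_raw, {"p_reveal_happy", "p_reveal_unhappy", "max_steps"}, "environment"
    )
    table_raw = raw["belief_update_table"]
    table = {}
    for k, v in table_raw.items():
        _check_keys(dict(v), {"fixed", "malleable"}, f"belief_update_table[{k}]")
        table[int(k)] = {m: float(p) for m, p in v.items()}
    if set(table) != {-2, -1, 0, 1, 2}:
        raise ValueError("belief_update_table must cover current values -2..2")
    environment = EnvironmentConfig(
        p_reveal_happy=float(env_raw["p_reveal_happy"]),
        p_reveal_unhappy=float(env_raw["p_reveal_unhappy"]),
        max_steps=int(env_raw["max_steps"]),
        update_table=table,
    )
    profiles = {}
    for label, p in raw["profiles"].items():
        p = dict(p)
        _check_keys(
            p,
            {
                "initial_beliefs",
                "belief_reward_bands",
                "time_cost",
                "water_reward",
                "subjective_update",
            },
            f"profiles.{label}",
        )
        profiles[label] = MindsetProfile(
            label=label,
            initial_beliefs=tuple(int(b) for b in p["initial_beliefs"]),
            belief_reward_bands=tuple(float(b) for b in p["belief_reward_bands"]),
            time_cost=float(p["time_cost"]),
            water_reward=float(p.get("water_reward", 5.0)),
            subjective_update=p.get("subjective_update", "mindset_rule"),
        )
    if set(profiles) != {"fixed", "malleable"}:
        raise ValueError("profiles must define exactly 'fixed' and 'malleable'")
    sim_raw = dict(raw["simulation"])
    _check_keys(
        sim_raw,
        {
            "n_players_per_mindset",
            "runs_per_player",
            "gamma",
            "planning_beta",
            "backup",
            "tol",
            "max_iter",
        },
        "simulation",
    )
    simulation = SimulationConfig(
        n_players_per_mindset=int(sim_raw["n_players_per_mindset"]),
        runs_per_player=int(sim_raw["runs_per_player"]),
        master_seed=int(raw["master_seed"]),
        environment=environment,
        gamma=float(sim_raw["gamma"]),
        planning_beta=float(sim_raw["planning_beta"]),
        backup=str(sim_raw["backup"]),
        tol=float(sim_raw["tol"]),
        max_iter=int(sim_raw["max_iter"]),
    )
    cls_raw = dict(raw["classification"])
    _check_keys(
        cls_raw,
        {"log_beta_min", "log_beta_max", "log_beta_step", "oracle_beta"},
        "classification",
    )
    lo, hi, step = (
        float(cls_raw["log_beta_min"]),
        float(cls_raw["log_beta_max"]),
        float(cls_raw["log_beta_step"]),
    )
    beta_grid = np.exp(np.arange(lo, hi + 1e-9, step))
    return RunConfig(
        version=int(raw["version"]),
        master_seed=int(raw["master_seed"]),
        output_dir=str(raw["output_dir"]),
        environment=environment,
        profiles=profiles,
        simulation=simulation,
        beta_grid=beta_grid,
        oracle_beta=bool(cls_raw["oracle_beta"]),
    )


def _default_raw() -> dict:
    text = (
        importlib.resources.files("mindsim").joinpath("data/default_config.yaml")
    ).read_text()
    return yaml.safe_load(text)


def default_config() -> RunConfig:
    return _from_dict(_default_raw())


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a run config: packaged defaults, optionally merged with a YAML file.

    ``overrides`` are top-level scalar overrides (e.g. ``master_seed=7``).
    """
    raw = _default_raw()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        raw = _deep_merge(raw, user)
    raw.update(overrides)
    return _from_dict(raw)
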