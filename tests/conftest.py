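"""Shared fixtures: solved Q tables and a desk-scale cohort (session scope)."""

from __future__ import annotations

import numpy as np
import pytest

from mindsim.profiles import FIXED_PROFILE, MALLEABLE_PROFILE
from mindsim.simulation import scaled_config, simulate_cohort, solve_all_profiles
from mindsim.water_task import EnvironmentConfig

SCALED_SEED = 20260101


@pytest.fixture(scope="session")
def default_env() -> EnvironmentConfig:
    return EnvironmentConfig()


@pytest.fixture(scope="session")
def sim_config(default_env):
    return scaled_config(master_seed=SCALED_SEED, environment=default_env)


@pytest.fixture(scope="session")
def q_tables(sim_config):
    """Solved Q tables for both profiles under the default environment."""
    return solve_all_profiles(sim_config)


@pytest.fixture(scope="session")
def scaled_cohort(sim_config, q_tables):
    """Desk-scale cohort: 50 player pairs x 20 runs = 2000 records."""
    records = simulate_cohort(sim_config, q_tables)
    assert len(records) == 2 * 50 * 20
    return records

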