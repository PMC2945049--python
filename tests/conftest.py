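"""Shared fixtures: small default cohorts and deterministic generators."""

import numpy as np
import pandas as pd
import pytest

from poolgwas import SimulationConfig
from poolgwas.simulate import (
    assign_pools,
    pool_metadata,
    simulate_probe_intensities,
    simulate_screening_cohort,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=42, n_snps=30)


@pytest.fixture(scope="session")
def screening_cohort(default_config) -> pd.DataFrame:
    return simulate_screening_cohort(default_config)


@pytest.fixture(scope="session")
def pools(screening_cohort, default_config) -> pd.DataFrame:
    return assign_pools(screening_cohort, default_config.pool_size)


@pytest.fixture(scope="session")
def pool_meta(pools) -> pd.DataFrame:
    return pool_metadata(pools)


@pytest.fixture(scope="session")
def probe_table(pools, screening_cohort, default_config) -> pd.DataFrame:
    return simulate_probe_intensities(pools, screening_cohort, default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
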