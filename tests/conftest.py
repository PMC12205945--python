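import numpy as np
import pytest

from twinlocal.synthetic import (
    SimulationConfig,
    simulate_twin_cohort,
    truth_from_proportions,
)
from twinlocal.twin import TwinData


@pytest.fixture(scope="session")
def medium_cohort():
    """Complete-data cohort (no covariates, no missingness) for model tests."""
    cfg = SimulationConfig(
        n_mz_pairs=1000,
        n_dz_pairs=1000,
        cholesky_truth=truth_from_proportions(h2=0.5, c2=0.2, overlap=0.6),
        beta_age=0.0,
        beta_sex=0.0,
        beta_fd=0.0,
        p_missing_wave2=0.0,
        p_unpaired=0.0,
        seed=42,
    )
    df, truth = simulate_twin_cohort(cfg)
    return df, truth


@pytest.fixture(scope="session")
def medium_data(medium_cohort):
    df, _ = medium_cohort
    return TwinData.from_long(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
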