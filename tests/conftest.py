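import numpy as np
import pandas as pd
import pytest

from periorisk import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort_100k() -> pd.DataFrame:
    """One large cohort at generator defaults, shared across tests."""
    return generate_cohort(SyntheticCohortConfig(n_patients=100_000, seed=1))


@pytest.fixture(scope="session")
def cohort_20k() -> pd.DataFrame:
    return generate_cohort(SyntheticCohortConfig(n_patients=20_000, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def binomial_3se(p: float, n: int) -> float:
    """Three binomial standard errors — the sampling tolerance used when a
    simulated proportion is compared with its target."""
    return 3 * np.sqrt(p * (1 - p) / n)
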