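import numpy as np
import pandas as pd
import pytest

from immunomap import SimulationConfig, generate_cohorts


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_cohort1=200, n_cohort2=250, n_followup=60,
                            n_genes=200, n_modules=3, module_sizes=[40, 30, 20],
                            n_metabolites=40, n_assoc_metabolites_per_module=3,
                            n_snps=60, loading_mean=0.8, seed=7)


@pytest.fixture(scope="session")
def small_cohorts(small_config):
    return generate_cohorts(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_correlation(rng, n):
    """A valid correlation matrix from random data."""
    X = rng.normal(size=(n, 3 * n))
    C = np.corrcoef(X)
    return C


@pytest.fixture()
def covariates_frame(rng):
    n = 40
    return pd.DataFrame(
        {"age": rng.uniform(25, 74, n), "sex": rng.integers(0, 2, n).astype(float)},
        index=[f"s{i}" for i in range(n)])
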