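import numpy as np
import pandas as pd
import pytest

from mefv_origins.datasets import table1_cohort
from mefv_origins.logistic_model import FeatureTable
from mefv_origins.synthetic_cohort import paper_like_config, simulate_retained


@pytest.fixture(scope="session")
def table1():
    """The published genotype-prevalence table expanded to 1781 records."""
    return table1_cohort()


@pytest.fixture(scope="session")
def paper_sim():
    """One paper-like synthetic cohort (1800 ascertained referrals) plus its
    ground-truth config; shared across tests that only read it."""
    config = paper_like_config(seed=2024)
    cohort, config = simulate_retained(config, 1800)
    return cohort, config


@pytest.fixture
def random_table():
    """Factory for small random feature tables with both classes present."""

    def make(n=40, p=3, seed=0, signal=0.0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.random((n, p)), columns=[f"f{j}" for j in range(p)]
        )
        eta = signal * (X.iloc[:, 0] - 0.5)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        y[0], y[1] = 0, 1  # guarantee both classes
        return FeatureTable(X, y)

    return make
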