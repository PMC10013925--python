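import warnings

import numpy as np
import pandas as pd
import pytest

from pvalscan import CountSimConfig, simulate_count_experiment
from pvalscan.mining import ProcessedTable

# The count simulator intentionally produces degenerate t-test cells on
# constant low counts; scipy warns about the precision of those moments.
warnings.filterwarnings(
    "ignore", message="Precision loss occurred", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_count_table() -> ProcessedTable:
    """A modest simulated count experiment reused by several tests."""
    return simulate_count_experiment(
        CountSimConfig(n_features=2000, n_per_group=4, frac_de=0.2, seed=11))


@pytest.fixture()
def basemean_table() -> ProcessedTable:
    """Tiny hand-built table with a basemean expression column."""
    df = pd.DataFrame({
        "baseMean": [5.0, 10.0, 50.0],
        "pvalue": [0.01, 0.5, 0.9],
    })
    return ProcessedTable(df=df)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
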