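import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import methylscreen as ms
from methylscreen.expression_profiling import expression_ratio

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> ms.SyntheticConfig:
    """The study conditions: 500 genes, 11 lines + reference, 20 planted."""
    return ms.SyntheticConfig(n_genes=500, n_lines=11, n_planted=20, seed=42)


@pytest.fixture(scope="session")
def default_dataset(default_config) -> ms.SyntheticDataset:
    return ms.generate_dataset(default_config)


@pytest.fixture(scope="session")
def derived_views(default_dataset):
    """delta / expression-ratio / fold-change views of the default dataset."""
    ds = default_dataset
    ref = ds.config.reference_id
    delta = ms.compute_delta(ds.beta, ref)
    ratios = expression_ratio(ds.expression, ref)
    fc = ms.fold_change(ds.treated, ds.mock)
    return delta, ratios, fc


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def random_matrix(rng, n_rows, n_cols, low=0.0, high=100.0, prefix="g"):
    vals = rng.uniform(low, high, size=(n_rows, n_cols))
    return pd.DataFrame(
        vals,
        index=[f"{prefix}{i}" for i in range(n_rows)],
        columns=[f"s{j}" for j in range(n_cols)],
    )
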