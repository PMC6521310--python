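import numpy as np
import pandas as pd
import pytest

from mirstrat.diffexpr import moderated_t_test
from mirstrat.preprocess import normalize_log2, stratify
from mirstrat.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One medium synthetic cohort with planted target repression."""
    return generate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def deg_table(cohort):
    """DEG table from the shared cohort, high vs low miRNA quartile groups."""
    expr = normalize_log2(cohort.expression)
    strat = stratify(cohort.mirna, 0.25)
    return moderated_t_test(expr, strat)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_matrix(rng):
    """Random 50-gene x 12-sample non-negative expression matrix."""
    values = rng.lognormal(mean=2.0, sigma=1.0, size=(50, 12))
    return pd.DataFrame(
        values,
        index=[f"g{i:03d}" for i in range(50)],
        columns=[f"s{j:02d}" for j in range(12)],
    )
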