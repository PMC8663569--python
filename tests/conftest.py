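"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

from becdistill import CohortConfig, ExpressionMatrix, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study conditions (160 x 2000, 4 clusters)."""
    cfg = CohortConfig(seed=101)
    expr, meta, truth = generate_cohort(cfg)
    return cfg, expr, meta, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for unit tests (60 x 300)."""
    cfg = CohortConfig(
        n_samples=60,
        n_genes=300,
        n_de_genes_per_cluster=10,
        n_covariate_genes=10,
        seed=7,
    )
    expr, meta, truth = generate_cohort(cfg)
    return cfg, expr, meta, truth


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        rng.normal(7, 1, (20, 8)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{i}" for i in range(8)],
    )
    return ExpressionMatrix(df)
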