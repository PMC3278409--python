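import numpy as np
import pandas as pd
import pytest

from risis.io import ExpressionMatrix
from risis.preprocess import filter_variable_genes, quantile_normalize
from risis.synthetic import CohortSpec, PlantedSplit, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with one strong planted split (delta = 3 sigma)."""
    spec = CohortSpec(
        n_samples=80,
        n_genes=2500,
        n_duplicates=8,
        planted_splits=[PlantedSplit(fraction_g1=0.30, module_size=60, effect=3.0)],
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_filtered(small_cohort):
    """Normalized, variance-filtered matrix of the small cohort's unique samples."""
    mat = quantile_normalize(small_cohort.expression)
    keep = filter_variable_genes(mat, k=400)
    return mat.subset_genes(keep).subset_samples(small_cohort.unique_samples)


@pytest.fixture
def toy_matrix():
    """A deterministic 12-gene x 8-sample matrix with weak structure."""
    rng = np.random.default_rng(42)
    X = rng.normal(0.0, 1.0, size=(12, 8))
    X[:4, :3] += 1.5
    return ExpressionMatrix(
        pd.DataFrame(
            X,
            index=[f"g{i:02d}" for i in range(12)],
            columns=[f"s{j}" for j in range(8)],
        )
    )
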