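import numpy as np
import pandas as pd
import pytest

from riskpath.io_preprocess import ExpressionMatrix


def make_matrix(values, groups, tissue="tumor", genes=None, samples=None):
    """Small ExpressionMatrix from a 2-D array and a list of group labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{i}" for i in range(n_samples)]
    ann = pd.DataFrame(
        {"group": list(groups), "tissue": tissue},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples),
        ann,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_cohort_matrix(rng):
    """40 genes x 20 samples (14 good / 6 poor), standard normal."""
    return make_matrix(
        rng.standard_normal((40, 20)), ["good"] * 14 + ["poor"] * 6
    )
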