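"""Shared fixtures: reduced-size simulated datasets for fast unit tests."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cafkit.preprocess import QCParams
from cafkit.simulate import SimConfig, simulate_caf_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    # small enough for second-scale tests, large enough to separate the
    # planted populations
    return SimConfig(n_genes=600, n_cells_per_sample=120, seed=11)


@pytest.fixture(scope="session")
def small_qc() -> QCParams:
    # thresholds rescaled to the 600-gene toy universe
    return QCParams(min_genes=100, n_top_expressed=500, n_variable=300)


@pytest.fixture(scope="session")
def caf_small(small_config):
    return simulate_caf_dataset(small_config)


def make_adata(X, barcodes=None, genes=None, **obs_cols) -> ad.AnnData:
    """Build a minimal AnnData around a dense or sparse count matrix."""
    X = sp.csr_matrix(X)
    n, m = X.shape
    obs = pd.DataFrame(
        dict(obs_cols),
        index=pd.Index(
            barcodes if barcodes is not None else [f"C{i:03d}" for i in range(n)],
            name="barcode",
        ),
    )
    var = pd.DataFrame(
        index=pd.Index(
            genes if genes is not None else [f"G{j:03d}" for j in range(m)],
            name="gene",
        )
    )
    return ad.AnnData(X=X, obs=obs, var=var)
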