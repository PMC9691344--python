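"""Quality control, normalization, and variable-gene selection.

The filters mirror a strict per-sample UMI-doublet cut (the top fraction of
cells by total UMI within each sample), a minimum detected-gene threshold,
total-count normalization to 10^4 followed by a log2(1 + x) transform, and
coefficient-of-variation variable-gene selection among the most expressed
genes, restricted to genes detected in at least 1% of cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class QCParams:
    doublet_top_fraction: float = 0.0005
    min_genes: int = 1000
    scale_total: float = 1e4
    n_top_expressed: int = 5000
    n_variable: int = 1500
    min_cell_fraction: float = 0.01
    cv_on_log: bool = False  # CV scale for variable genes; linear is default

    def __post_init__(self) -> None:
        if not 0 <= self.doublet_top_fraction < 1:
            raise ValueError("doublet_top_fraction must be in [0, 1)")
        if self.n_variable > self.n_top_expressed:
            raise ValueError("n_variable must not exceed n_top_expressed")


def _total_counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel()
    return np.asarray(X).sum(axis=1)


def _genes_detected(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (np.asarray(X) > 0).sum(axis=1)


def remove_doublets_top_umi(
    adata: ad.AnnData, params: QCParams | None = None, sample_key: str = "sample"
) -> Tuple[ad.AnnData, List[str]]:
    """Drop the highest-total-UMI cells of each sample as putative doublets.

    Within each sample the ``ceil(doublet_top_fraction * n_cells)`` cells
    with the largest UMI totals are removed (none when the fraction is 0).
    Ties at the quota boundary are resolved by removing the
    lexicographically smaller barcode, so the filter is deterministic.
    Returns the filtered matrix and the removed barcodes.
    """
    params = params or QCParams()
    if sample_key not in adata.obs:
        raise ValueError(f"missing obs column {sample_key!r} with sample ids")
    if adata.obs[sample_key].isna().any():
        raise ValueError("every cell needs a sample id")
    totals = _total_counts(adata)
    removed: List[str] = []
    if params.doublet_top_fraction > 0:
        for sample, idx in adata.obs.groupby(sample_key, observed=True).indices.items():
            quota = math.ceil(params.doublet_top_fraction * len(idx))
            order = sorted(idx, key=lambda i: (-totals[i], adata.obs_names[i]))
            removed.extend(adata.obs_names[i] for i in order[:quota])
    keep = ~adata.obs_names.isin(removed)
    return adata[keep].copy(), sorted(removed)


def filter_min_genes(
    adata: ad.AnnData, params: QCParams | None = None
) -> ad.AnnData:
    """Keep cells detecting at least ``min_genes`` distinct genes."""
    params = params or QCParams()
    detected = _genes_detected(adata)
    keep = detected >= params.min_genes
    if not keep.any():
        warnings.warn("all cells fall below the min-genes threshold", stacklevel=2)
    return adata[keep].copy()


def normalize_log(adata: ad.AnnData, params: QCParams | None = None) -> ad.AnnData:
    """Total-count normalize to ``scale_total`` and log2(1 + x) transform.

    Raw counts are kept in ``layers["counts"]``; ``X`` becomes
    ``log2(1 + scale_total * count / cell_total)``.  Cells with zero total
    are rejected (run :func:`filter_min_genes` first).
    """
    params = params or QCParams()
    totals = _total_counts(adata)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total UMI cannot be normalized")
    out = adata.copy()
    X = sp.csr_matrix(out.X, dtype=np.float64)
    out.layers["counts"] = sp.csr_matrix(out.X).copy()
    scale = params.scale_total / totals
    X = sp.diags(scale) @ X
    X.data = np.log2(1.0 + X.data)
    out.X = X
    out.obs["total_counts"] = totals
    return out


def _linear_normalized(adata: ad.AnnData) -> sp.csr_matrix:
    """Linear-scale normalized values (scale_total * count / total)."""
    X = sp.csr_matrix(adata.X, dtype=np.float64).copy()
    X.data = np.exp2(X.data) - 1.0
    return X


def select_variable_genes(
    adata: ad.AnnData, params: QCParams | None = None
) -> List[str]:
    """Rank variable genes by coefficient of variation.

    Steps: (1) drop genes detected in fewer than ``min_cell_fraction`` of
    cells (detection counts strictly positive raw counts); (2) keep the
    ``n_top_expressed`` genes with highest mean linear normalized
    expression; (3) of those, return the ``n_variable`` genes with highest
    CV = sd/mean, sorted by CV descending.  The CV is computed on linear
    normalized values by default (``cv_on_log=True`` switches to the log
    scale).  If fewer genes are eligible than requested, all eligible genes
    are returned with a warning.
    """
    params = params or QCParams()
    n_cells = adata.n_obs
    counts = adata.layers.get("counts")
    if counts is None:
        counts = adata.X
    counts = sp.csr_matrix(counts)
    det_frac = np.asarray((counts > 0).sum(axis=0)).ravel() / max(n_cells, 1)
    eligible = det_frac >= params.min_cell_fraction

    lin = _linear_normalized(adata)
    lin_arr = np.asarray(lin.todense())
    mean = lin_arr.mean(axis=0)
    order_expr = np.argsort(-mean, kind="stable")
    top = [i for i in order_expr if eligible[i]][: params.n_top_expressed]

    vals = np.asarray(sp.csr_matrix(adata.X).todense()) if params.cv_on_log else lin_arr
    sub_mean = vals[:, top].mean(axis=0)
    sub_sd = vals[:, top].std(axis=0, ddof=1) if n_cells > 1 else np.zeros(len(top))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(sub_mean > 0, sub_sd / sub_mean, 0.0)
    if len(top) < params.n_variable:
        warnings.warn(
            f"only {len(top)} eligible genes for {params.n_variable} requested",
            stacklevel=2,
        )
    order_cv = np.argsort(-cv, kind="stable")[: params.n_variable]
    return [adata.var_names[top[i]] for i in order_cv]


def preprocess(
    adata: ad.AnnData, params: QCParams | None = None, sample_key: str = "sample"
) -> Tuple[ad.AnnData, List[str], List[str]]:
    """Full QC pipeline: doublet cut, min-genes filter, normalization,
    variable-gene selection.  Returns (normalized AnnData, removed doublet
    barcodes, variable gene list)."""
    params = params or QCParams()
    filtered, removed = remove_doublets_top_umi(adata, params, sample_key=sample_key)
    filtered = filter_min_genes(filtered, params)
    norm = normalize_log(filtered, params)
    var_genes = select_variable_genes(norm, params)
    return norm, removed, var_genes
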