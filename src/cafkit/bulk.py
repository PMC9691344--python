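"""Bulk RNA-seq silencing analysis: DE, z-scores, and GO-BP enrichment.

The differential-expression call delegates to the count-based engine
(replicates are the libraries); genes pass at adjusted P < 0.01 and
absolute fold-change > 2.  Expression heatmap values are per-gene z-scores
of log2(x + 1)-transformed TMM-normalized counts.  Functional enrichment
is an upper-tail hypergeometric test per term of a user-provided
collection, restricted to terms containing at least three DE genes.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust, nb_lrt, tmm_factors


def bulk_de(
    counts: pd.DataFrame,
    conditions: Sequence[str],
    group_a: str,
    group_b: str,
    max_padj: float = 0.01,
    min_fc: float = 2.0,
) -> Tuple[pd.DataFrame, List[str]]:
    """Two-condition DE on a genes x samples count table.

    Returns the full per-gene result table (fold-changes of ``group_a``
    over ``group_b``) and the significant gene list at adjusted
    P < ``max_padj`` and |FC| > ``min_fc`` (both strict).
    """
    conditions = np.asarray(conditions)
    if conditions.shape[0] != counts.shape[1]:
        raise ValueError("one condition label per sample column is required")
    for g in (group_a, group_b):
        if (conditions == g).sum() < 2:
            raise ValueError(f"condition {g!r} needs at least 2 replicates")
    sel = np.isin(conditions, [group_a, group_b])
    mat = counts.loc[:, sel].to_numpy(dtype=np.float64).T  # samples x genes
    groups = np.where(conditions[sel] == group_a, "A", "B")
    res = nb_lrt(mat, groups, genes=list(counts.index))
    min_l2 = np.log2(min_fc)
    sig = res[(res["p_adj"] < max_padj) & (res["log2FC"].abs() > min_l2)]
    return res, list(sig.index)


def zscore_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores of log2(x+1) TMM-normalized counts across samples.

    Counts are scaled by effective library size (total x TMM factor, per
    million), log2(x + 1) transformed, then standardized per gene with the
    sample standard deviation (n - 1).  Constant genes map to all-zero
    rows by convention.
    """
    mat = counts.to_numpy(dtype=np.float64)
    factors = tmm_factors(mat.T)
    eff = mat.sum(axis=0) * factors
    norm = mat / eff[None, :] * 1e6
    logv = np.log2(norm + 1.0)
    mean = logv.mean(axis=1, keepdims=True)
    sd = logv.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (logv - mean) / sd, 0.0)
    return pd.DataFrame(z, index=counts.index, columns=counts.columns)


def go_enrichment(
    de_genes: Sequence[str] | Set[str],
    universe: Sequence[str] | Set[str],
    terms: Dict[str, Tuple[str, List[str]]],
    min_de_in_term: int = 3,
    adjust: bool = True,
) -> pd.DataFrame:
    """Hypergeometric enrichment of the DE set in each term of a collection.

    Only terms containing at least ``min_de_in_term`` DE genes are tested
    (and reported).  Term gene sets are intersected with the universe; the
    p-value is the upper tail of drawing at least the observed overlap
    when |DE| genes are sampled from the universe without replacement.
    BH-adjusted p-values are reported alongside but the count gate uses
    raw membership, mirroring the published procedure.
    """
    universe = set(universe)
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    M, N = len(universe), len(de)
    rows = []
    for term, (desc, genes) in terms.items():
        term_set = set(genes) & universe
        if not term_set:
            continue
        overlap = len(term_set & de)
        if overlap < min_de_in_term:
            continue
        p = float(hypergeom.sf(overlap - 1, M, len(term_set), N))
        rows.append(
            {
                "term": term,
                "description": desc,
                "n_de_in_term": overlap,
                "term_size": len(term_set),
                "p_raw": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "description", "n_de_in_term", "term_size", "p_raw"]
    )
    if adjust and len(out):
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out = out.sort_values("p_raw", kind="stable").set_index("term")
    return out
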