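"""Ligand-receptor interaction scoring and population-bias selection.

A pair's score between a source and a target population is the
regularized product score = sqrt(l*r) / (mu + sqrt(l*r)), with l and r the
mean log-normalized ligand/receptor expression in the source and target
populations and mu the mean of the whole log-normalized matrix over the
cells participating in that sample's comparison.  One score is computed
per sample; an interaction is "reliable" when the median over samples is
strictly above 0.5.  A pair is biased toward source population A over B
when the difference of the two medians is strictly above 0.1, the larger
median clears the reliability threshold, and the gated gene (the ligand
for CAF-to-cancer, the receptor for cancer-to-CAF) is differentially
expressed toward A (adjusted P < 1%, FC > 2).
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp


def lr_score(l: float, r: float, mu: float) -> float:
    """Regularized ligand-receptor score in [0, 1).

    Monotone non-decreasing in both expression means, zero iff either is
    zero, and exactly 0.5 when sqrt(l*r) equals the regularizer mu.
    """
    if l < 0 or r < 0:
        raise ValueError("expression means must be non-negative")
    if mu <= 0:
        raise ValueError("the regularizer mu must be positive")
    root = np.sqrt(l * r)
    return float(root / (mu + root))


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)


def validate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Check the pair table: ligand/receptor columns, no duplicate rows."""
    for col in ("ligand", "receptor"):
        if col not in pairs.columns:
            raise ValueError(f"pair table lacks a {col!r} column")
    if pairs.duplicated(subset=["ligand", "receptor"]).any():
        raise ValueError("duplicate (ligand, receptor) rows in pair table")
    return pairs


def score_all(
    adata,
    pairs: pd.DataFrame,
    source_pop: str,
    target_pop: str,
    population_key: str = "population",
    sample_key: str = "sample",
    min_cells: int = 10,
) -> pd.DataFrame:
    """Score every LR pair from one source to one target population.

    ``adata`` holds log-normalized expression for all cells of both
    populations with ``obs[population_key]`` and ``obs[sample_key]``.
    Each sample where both populations have at least ``min_cells`` cells
    contributes one score; the regularizer mu is the mean of that
    sample's participating cells over all genes.  Pairs whose ligand or
    receptor is absent from the matrix are skipped with a warning.
    Returns one row per pair: per-sample scores, ``median_score`` over
    contributing samples, ``n_samples``, and ``reliable`` (median > 0.5).
    """
    validate_pairs(pairs)
    pops = adata.obs[population_key].to_numpy()
    samples = adata.obs[sample_key].to_numpy()
    sample_names = list(pd.unique(samples))
    gene_index = {g: i for i, g in enumerate(adata.var_names)}

    keep_rows, skipped = [], []
    for _, row in pairs.iterrows():
        if row["ligand"] in gene_index and row["receptor"] in gene_index:
            keep_rows.append(row)
        else:
            skipped.append((row["ligand"], row["receptor"]))
    if skipped:
        warnings.warn(
            f"{len(skipped)} pair(s) with genes absent from the matrix skipped",
            stacklevel=2,
        )

    per_sample: Dict[str, Optional[Tuple[np.ndarray, np.ndarray, float]]] = {}
    for s in sample_names:
        src = (samples == s) & (pops == source_pop)
        tgt = (samples == s) & (pops == target_pop)
        if src.sum() < min_cells or tgt.sum() < min_cells:
            per_sample[s] = None
            continue
        X_src = _dense(adata.X[src])
        X_tgt = _dense(adata.X[tgt])
        l_means = X_src.mean(axis=0)
        r_means = X_tgt.mean(axis=0)
        mu = float(np.vstack([X_src, X_tgt]).mean())
        per_sample[s] = (l_means, r_means, mu)

    records = []
    for row in keep_rows:
        li, ri = gene_index[row["ligand"]], gene_index[row["receptor"]]
        scores = {}
        vals = []
        for s in sample_names:
            stats = per_sample[s]
            if stats is None:
                scores[f"score_{s}"] = np.nan
                continue
            l_means, r_means, mu = stats
            sc = lr_score(l_means[li], r_means[ri], mu)
            scores[f"score_{s}"] = sc
            vals.append(sc)
        median = float(np.median(vals)) if vals else np.nan
        records.append(
            {
                "ligand": row["ligand"],
                "receptor": row["receptor"],
                "source": source_pop,
                "target": target_pop,
                **scores,
                "median_score": median,
                "n_samples": len(vals),
                "reliable": bool(median > 0.5) if vals else False,
            }
        )
    return pd.DataFrame(records)


def count_interactions(
    records: pd.DataFrame, include_autocrine: bool = True
) -> pd.DataFrame:
    """Source x target matrix counting reliable interactions.

    Counts records with ``reliable == True`` per directed (source, target)
    population pair; autocrine (source == target) records are excluded
    when ``include_autocrine`` is False.
    """
    if records.empty:
        return pd.DataFrame()
    rel = records[records["reliable"].astype(bool)]
    if not include_autocrine:
        rel = rel[rel["source"] != rel["target"]]
    sources = sorted(pd.unique(records["source"]))
    targets = sorted(pd.unique(records["target"]))
    table = pd.DataFrame(0, index=pd.Index(sources, name="source"), columns=targets)
    for (src, tgt), grp in rel.groupby(["source", "target"], observed=True):
        table.loc[src, tgt] = len(grp)
    return table


def biased_interactions(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    de_a_vs_b: pd.DataFrame,
    gate_gene: str = "ligand",
    delta: float = 0.1,
    fdr: float = 0.01,
    fc: float = 2.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split pairs into A-biased and B-biased interaction sets.

    ``records_a`` and ``records_b`` score the same pairs from source
    population A and B against the same target.  A pair is A-biased iff
    median_A - median_B > ``delta`` (strict), median_A > 0.5, and the
    gated gene (``gate_gene`` column: "ligand" for the CAF-to-cancer
    direction, "receptor" for cancer-to-CAF) is differentially expressed
    toward A in ``de_a_vs_b`` (log2FC of A over B) with adjusted
    P < ``fdr`` and FC > ``fc``, both strict; symmetrically for B.  The
    two sets are disjoint by construction.
    """
    key = ["ligand", "receptor"]
    merged = records_a.merge(
        records_b, on=key, suffixes=("_a", "_b"), validate="one_to_one"
    )
    if (merged["target_a"] != merged["target_b"]).any():
        raise ValueError("both directions must target the same population")
    min_l2 = np.log2(fc)
    rows_a, rows_b = [], []
    for _, row in merged.iterrows():
        gene = row[gate_gene]
        if gene not in de_a_vs_b.index:
            continue
        d = row["median_score_a"] - row["median_score_b"]
        de = de_a_vs_b.loc[gene]
        if (
            d > delta
            and row["median_score_a"] > 0.5
            and de["log2FC"] > min_l2
            and de["p_adj"] < fdr
        ):
            rows_a.append({**row[key].to_dict(), "delta": d})
        elif (
            -d > delta
            and row["median_score_b"] > 0.5
            and -de["log2FC"] > min_l2
            and de["p_adj"] < fdr
        ):
            rows_b.append({**row[key].to_dict(), "delta": -d})
    cols = key + ["delta"]
    return (
        pd.DataFrame(rows_a, columns=cols),
        pd.DataFrame(rows_b, columns=cols),
    )
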