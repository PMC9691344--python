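"""Consensus marker gene signatures for nested cluster hierarchies.

A gene enters a subpopulation signature only if it is expressed in at
least 20% of that cluster's cells and shows fold-change >= 2 at adjusted
P <= 1% against the other clusters pooled AND against each of them
individually; the top 30 genes by pooled fold-change are kept.  Main
populations additionally require 10% expression in each of their own
subclusters, with gates taken against the other main cluster and its two
subclusters and ranking by the main-vs-main fold-change.  The reference
atlas uses the subcluster rule over three flat clusters with top 16.
Because the fold-change gate is directional, signatures of sibling
clusters are provably disjoint; this is re-asserted at run time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom


@dataclass
class GeneSignature:
    cluster: str
    rule: str  # "sub" | "main" | "atlas"
    table: pd.DataFrame  # index gene; columns rank_fc (log2), p_adj, frac

    @property
    def genes(self) -> List[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def _passes(de: pd.DataFrame, min_log2fc: float, max_padj: float) -> pd.Series:
    """Directional gate: up-regulated in the signature's cluster (group A)."""
    return (de["log2FC"] >= min_log2fc) & (de["p_adj"] <= max_padj)


def subcluster_signature(
    cluster: str,
    de_vs_pooled: pd.DataFrame,
    de_vs_each: Sequence[pd.DataFrame],
    min_frac: float = 0.20,
    min_fc: float = 2.0,
    max_padj: float = 0.01,
    k: int = 30,
    rule: str = "sub",
) -> GeneSignature:
    """Consensus signature of one subcluster against its siblings.

    ``de_vs_pooled`` contrasts the cluster (group A) against all siblings
    pooled; ``de_vs_each`` holds one contrast per sibling.  A gene is kept
    iff expressed in >= ``min_frac`` of the cluster's cells and passes
    FC >= ``min_fc`` at adjusted P <= ``max_padj`` in every contrast; the
    top ``k`` genes by pooled fold-change are returned, FC-descending.
    """
    if not de_vs_each:
        raise ValueError("at least one pairwise contrast is required")
    min_l2 = np.log2(min_fc)
    keep = (de_vs_pooled["frac_A"] >= min_frac) & _passes(
        de_vs_pooled, min_l2, max_padj
    )
    for de in de_vs_each:
        aligned = de.reindex(de_vs_pooled.index)
        keep &= _passes(aligned, min_l2, max_padj).fillna(False)
    passed = de_vs_pooled[keep].sort_values("log2FC", ascending=False, kind="stable")
    top = passed.head(k)
    table = pd.DataFrame(
        {
            "rank_fc": top["log2FC"],
            "p_adj": top["p_adj"],
            "frac": top["frac_A"],
        }
    )
    return GeneSignature(cluster=cluster, rule=rule, table=table)


def main_signature(
    cluster: str,
    de_vs_other_main: pd.DataFrame,
    de_vs_other_subs: Sequence[pd.DataFrame],
    own_sub_fracs: Dict[str, pd.Series],
    min_frac_main: float = 0.20,
    min_frac_sub: float = 0.10,
    min_fc: float = 2.0,
    max_padj: float = 0.01,
    k: int = 30,
) -> GeneSignature:
    """Consensus signature of one main cluster.

    Gates: expression in >= 20% of the main cluster's cells
    (``de_vs_other_main`` frac_A) and >= 10% of each of its own
    subclusters (``own_sub_fracs``: subcluster -> per-gene expression
    fraction), with the FC/adjusted-P gate against the other main cluster
    and against each of the other main cluster's subclusters
    (``de_vs_other_subs``).  Ranked by the main-vs-main fold-change.
    """
    min_l2 = np.log2(min_fc)
    keep = (de_vs_other_main["frac_A"] >= min_frac_main) & _passes(
        de_vs_other_main, min_l2, max_padj
    )
    for name, fracs in own_sub_fracs.items():
        keep &= fracs.reindex(de_vs_other_main.index).fillna(0.0) >= min_frac_sub
    for de in de_vs_other_subs:
        aligned = de.reindex(de_vs_other_main.index)
        keep &= _passes(aligned, min_l2, max_padj).fillna(False)
    passed = de_vs_other_main[keep].sort_values(
        "log2FC", ascending=False, kind="stable"
    )
    top = passed.head(k)
    table = pd.DataFrame(
        {"rank_fc": top["log2FC"], "p_adj": top["p_adj"], "frac": top["frac_A"]}
    )
    return GeneSignature(cluster=cluster, rule="main", table=table)


def atlas_signature(
    cluster: str,
    de_vs_pooled: pd.DataFrame,
    de_vs_each: Sequence[pd.DataFrame],
    k: int = 16,
    **kwargs,
) -> GeneSignature:
    """Subcluster rule over flat atlas clusters, top 16 by fold-change."""
    return subcluster_signature(
        cluster, de_vs_pooled, de_vs_each, k=k, rule="atlas", **kwargs
    )


def assert_disjoint(signatures: Iterable[GeneSignature]) -> None:
    """Sibling signatures must not share genes (directional FC gates)."""
    sigs = list(signatures)
    for i in range(len(sigs)):
        for j in range(i + 1, len(sigs)):
            shared = set(sigs[i].genes) & set(sigs[j].genes)
            if shared:
                raise AssertionError(
                    f"signatures {sigs[i].cluster} and {sigs[j].cluster} "
                    f"share genes: {sorted(shared)[:5]}"
                )


def check_signature_gates(
    sig: GeneSignature,
    de_vs_pooled: pd.DataFrame,
    de_vs_each: Sequence[pd.DataFrame],
    min_frac: float = 0.20,
    min_fc: float = 2.0,
    max_padj: float = 0.01,
) -> bool:
    """Independent validator: every emitted gene satisfies every gate."""
    min_l2 = np.log2(min_fc)
    for gene in sig.genes:
        row = de_vs_pooled.loc[gene]
        if row["frac_A"] < min_frac:
            return False
        if row["log2FC"] < min_l2 or row["p_adj"] > max_padj:
            return False
        for de in de_vs_each:
            if gene not in de.index:
                return False
            r = de.loc[gene]
            if r["log2FC"] < min_l2 or r["p_adj"] > max_padj:
                return False
    return True


def signature_overlap_test(
    sig_a: Set[str] | Sequence[str],
    sig_b: Set[str] | Sequence[str],
    universe_size: int,
) -> Tuple[int, float]:
    """Hypergeometric test of the overlap between two gene sets.

    Returns (overlap count, upper-tail probability of an overlap at least
    this large when |A| genes are drawn without replacement from a
    universe containing |B| marked genes).
    """
    a, b = set(sig_a), set(sig_b)
    if universe_size < len(a) or universe_size < len(b):
        raise ValueError("universe smaller than a signature")
    overlap = len(a & b)
    p = float(hypergeom.sf(overlap - 1, universe_size, len(b), len(a)))
    return overlap, p


def score_signature_on_cells(adata, sig: GeneSignature | Sequence[str]) -> pd.Series:
    """Mean log-normalized expression of the signature genes per cell."""
    genes = list(sig.genes if isinstance(sig, GeneSignature) else sig)
    if not genes:
        raise ValueError("empty signature")
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing[:5]}")
    sub = adata[:, genes].X
    vals = np.asarray(sub.todense()) if sp.issparse(sub) else np.asarray(sub)
    return pd.Series(vals.mean(axis=1), index=adata.obs_names, name="signature_score")


def signatures_to_gmt(
    signatures: Iterable[GeneSignature],
) -> Dict[str, Tuple[str, List[str]]]:
    """Export signatures as a GMT-style mapping for interoperability."""
    return {
        f"{s.rule}:{s.cluster}": (f"{s.rule} signature of {s.cluster}", s.genes)
        for s in signatures
    }


def derive_nested_signatures(
    adata,
    sub_key: str = "sub",
    main_key: str = "main",
    k_sub: int = 30,
    k_main: int = 30,
    alpha: Optional[float] = None,
) -> Dict[str, GeneSignature]:
    """Derive all subpopulation and main-population signatures of a dataset.

    ``adata`` carries raw counts in ``layers["counts"]`` (or ``X``) and the
    nested cluster assignment in ``obs``.  Runs every required DE contrast
    through the engine and applies the consensus rules; sibling disjointness
    is asserted before returning.
    """
    from .de import dataset_dispersion, de_between

    obs = adata.obs
    if alpha is None:
        alpha = dataset_dispersion(adata, obs[sub_key].to_numpy())
    subs = list(pd.unique(obs[sub_key]))
    mains = list(pd.unique(obs[main_key]))
    sub_labels = obs[sub_key].to_numpy()
    main_labels = obs[main_key].to_numpy()

    out: Dict[str, GeneSignature] = {}
    for target in subs:
        pooled_labels = np.where(sub_labels == target, target, "__rest__")
        de_pooled = de_between(adata, pooled_labels, target, "__rest__", alpha=alpha)
        de_each = [
            de_between(adata, sub_labels, target, other, alpha=alpha)
            for other in subs
            if other != target
        ]
        out[target] = subcluster_signature(target, de_pooled, de_each, k=k_sub)
    assert_disjoint(out[s] for s in subs)

    counts = adata.layers.get("counts", adata.X)
    counts = sp.csr_matrix(counts)
    for target in mains:
        other = [m for m in mains if m != target][0]
        de_main = de_between(adata, main_labels, target, other, alpha=alpha)
        other_subs = [s for s in subs if main_labels[sub_labels == s][0] == other]
        de_vs_other_subs = [
            de_between(
                adata,
                np.where(main_labels == target, target, sub_labels),
                target,
                s,
                alpha=alpha,
            )
            for s in other_subs
        ]
        own_subs = [s for s in subs if main_labels[sub_labels == s][0] == target]
        own_fracs = {}
        for s in own_subs:
            mask = sub_labels == s
            frac = np.asarray((counts[mask] > 0).mean(axis=0)).ravel()
            own_fracs[s] = pd.Series(frac, index=adata.var_names)
        out[target] = main_signature(
            target, de_main, de_vs_other_subs, own_fracs, k=k_main
        )
    assert_disjoint(out[m] for m in mains)
    return out
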