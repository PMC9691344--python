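"""PCA, optional t-SNE, and nested Ward hierarchical clustering.

Clustering operates directly on log-normalized expression over the variable
genes (Euclidean distance, Ward linkage); the dendrogram is cut at k=2 for
the main populations and k=4 for the subpopulations, and the k=4 labels
nest strictly within the k=2 labels.  The 30-component PCA feeds t-SNE
only — it plays no role in clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)


def pca_embed(X, n_pc: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Project cells onto the top principal components of the gene-centered
    matrix.  Genes are centered but not scaled to unit variance.  Returns
    (cells x n_pc coordinates, explained variance per component)."""
    X = _dense(X)
    if X.shape[0] < n_pc + 1:
        raise ValueError(f"need at least {n_pc + 1} cells for {n_pc} components")
    model = PCA(n_components=n_pc, svd_solver="full")
    coords = model.fit_transform(X)
    return coords, model.explained_variance_


def tsne_embed(
    pcs: np.ndarray, perplexity: float = 30.0, seed: int = 0
) -> np.ndarray:
    """2-D t-SNE layout of the PCA coordinates (visualization plumbing).

    The perplexity is clamped below (n_cells - 1) / 3 with a warning when
    the input is too small for the requested value."""
    n = pcs.shape[0]
    max_perp = max((n - 1) / 3.0, 1.0)
    if perplexity >= max_perp:
        warnings.warn(
            f"perplexity {perplexity} too large for {n} cells; using {max_perp:.1f}",
            stacklevel=2,
        )
        perplexity = max_perp
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return tsne.fit_transform(np.asarray(pcs, dtype=np.float64))


@dataclass
class ClusterTree:
    """Ward dendrogram with nested cuts.

    ``linkage`` is the scipy (n-1) x 4 merge table; ``cuts`` maps k to
    integer labels (1..k, renumbered by first cell occurrence so labels are
    deterministic under cell permutation up to relabeling)."""

    linkage: np.ndarray
    cuts: Dict[int, np.ndarray] = field(default_factory=dict)

    def sub_to_main(self) -> Dict[int, int]:
        """Map each k=4 label to the k=2 label containing it."""
        if 2 not in self.cuts or 4 not in self.cuts:
            raise ValueError("both k=2 and k=4 cuts are required")
        mapping: Dict[int, int] = {}
        for sub, main in zip(self.cuts[4], self.cuts[2]):
            if sub in mapping and mapping[sub] != main:
                raise AssertionError("k=4 labels do not nest within k=2 labels")
            mapping[sub] = main
        return mapping


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k in order of first appearance."""
    out = np.empty_like(labels)
    seen: Dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        out[i] = seen[lab]
    return out


def ward_cluster(X, ks: tuple[int, ...] = (2, 4)) -> ClusterTree:
    """Ward-linkage hierarchical clustering on Euclidean distances.

    ``X`` is the cells x variable-genes log-normalized matrix.  Cuts are
    taken by cluster count; the k=4 cut refines the k=2 cut by dendrogram
    construction, and this nesting is re-checked on every call."""
    X = _dense(X)
    n = X.shape[0]
    if n < max(ks):
        raise ValueError(f"need at least {max(ks)} cells for a k={max(ks)} cut")
    Z = sch.linkage(X, method="ward")
    heights = Z[:, 2]
    if np.any(np.diff(heights) < -1e-9 * max(heights.max(), 1.0)):
        raise AssertionError("non-monotone merge heights in Ward linkage")
    tree = ClusterTree(linkage=Z)
    for k in ks:
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
        tree.cuts[k] = _renumber(labels)
    if 2 in tree.cuts and 4 in tree.cuts:
        tree.sub_to_main()  # raises if the cuts fail to nest
    return tree
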