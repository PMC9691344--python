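"""Two-group differential expression on raw counts.

The engine combines trimmed-mean-of-M-values (TMM) library normalization,
a negative-binomial likelihood-ratio test with a single common dispersion
estimated by Cox-Reid adjusted profile likelihood over all genes, and
Benjamini-Hochberg correction.  It serves both single-cell cluster
contrasts (each cell is one library) and bulk replicate contrasts.

Model: y_gi ~ NB(mu_gi, alpha) with Var = mu + alpha*mu^2 and
mu_gi = s_i * lambda_{g, group(i)}, where s_i is the effective library
size (raw total x TMM factor).  The LRT compares the two-group-mean fit
against a common-mean null; the statistic is referred to chi-square(1).
Genes with zero counts in every observation carry no information: they are
flagged, given p = 1 and log2FC = 0, and excluded from the BH denominator.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2, rankdata

_ETA_MIN, _ETA_MAX = -25.0, 25.0


# --------------------------------------------------------------------- #
# TMM normalization


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """Scale factor of one library against the reference.

    Doubly trimmed (30% on M-values, 5% on A-values) precision-weighted
    mean of the M-values over genes positive in both libraries."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    return float(2.0 ** (np.sum(log_r[keep] * w) / np.sum(w)))


def tmm_factors(counts: np.ndarray) -> np.ndarray:
    """TMM scale factors for a libraries x genes count matrix.

    The reference library is the one whose 75th count-fraction percentile
    is closest to the mean across libraries; factors are normalized to
    geometric mean 1.  A library with all-zero counts is an error.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need at least two libraries")
    lib_sizes = counts.sum(axis=1)
    zero = np.flatnonzero(lib_sizes == 0)
    if zero.size:
        raise ValueError(f"library {zero[0]} has all-zero counts")
    f75 = np.quantile(counts / lib_sizes[:, None], 0.75, axis=1)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(counts[i], counts[ref], lib_sizes[i], lib_sizes[ref])
            for i in range(counts.shape[0])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# --------------------------------------------------------------------- #
# NB fitting


def _fit_means(
    y: np.ndarray, s: np.ndarray, alpha: float, n_iter: int = 25, tol: float = 1e-10
) -> np.ndarray:
    """Per-gene NB mean rate by Fisher scoring on eta = log(lambda).

    ``y`` is genes x observations, ``s`` the effective library sizes;
    returns lambda (counts per unit effective library size) per gene.
    """
    tot = y.sum(axis=1)
    eta = np.log(np.clip(tot, 0.01, None) / s.sum())
    eta = np.clip(eta, _ETA_MIN, _ETA_MAX)
    for _ in range(n_iter):
        mu = np.exp(eta)[:, None] * s[None, :]
        score = (y - mu * (1.0 + alpha * y) / (1.0 + alpha * mu)).sum(axis=1)
        info = (mu / (1.0 + alpha * mu)).sum(axis=1)
        step = score / np.clip(info, 1e-12, None)
        step = np.clip(step, -5.0, 5.0)
        eta = np.clip(eta + step, _ETA_MIN, _ETA_MAX)
        if np.max(np.abs(step)) < tol:
            break
    return np.exp(eta)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Per-gene NB log-likelihood (terms constant in mu and alpha dropped)."""
    inv = 1.0 / alpha
    mu = np.clip(mu, 1e-12, None)
    return (
        gammaln(y + inv)
        - gammaln(inv)
        + y * np.log(alpha * mu / (1.0 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    ).sum(axis=1)


def estimate_common_dispersion(
    y: np.ndarray,
    s: np.ndarray,
    groups: np.ndarray,
    bounds: Tuple[float, float] = (1e-6, 50.0),
    max_genes: int = 1000,
) -> float:
    """Common NB dispersion by Cox-Reid adjusted profile likelihood.

    Maximizes, over log(alpha), the sum across genes of the group-means
    model profile log-likelihood minus half the log determinant of the
    per-group Fisher information (the Cox-Reid degrees-of-freedom
    adjustment).  When more than ``max_genes`` genes are available the
    profile is summed over an evenly spaced deterministic subsample —
    a shared dispersion needs far fewer genes than the matrix carries.
    """
    if y.shape[0] > max_genes:
        idx = np.linspace(0, y.shape[0] - 1, max_genes).astype(int)
        y = y[idx]
    labels = np.unique(groups)
    masks = [groups == g for g in labels]

    def neg_apl(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        total = 0.0
        for m in masks:
            lam = _fit_means(y[:, m], s[m], alpha)
            mu = lam[:, None] * s[m][None, :]
            ll = _nb_loglik(y[:, m], mu, alpha)
            info = (mu / (1.0 + alpha * mu)).sum(axis=1)
            total += float(np.sum(ll - 0.5 * np.log(np.clip(info, 1e-12, None))))
        return -total

    res = minimize_scalar(
        neg_apl,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def dataset_dispersion(data, labels: Sequence) -> float:
    """Common dispersion of a whole dataset under a given grouping.

    Convenience wrapper used to estimate the dispersion once per dataset
    (e.g. on the four subpopulations) and share it across all contrasts.
    ``data`` is an AnnData with raw counts in ``layers["counts"]``/``X``
    or an observations x genes array.
    """
    if isinstance(data, ad.AnnData):
        counts = data.layers.get("counts", data.X)
    else:
        counts = data
    counts = np.asarray(
        counts.todense() if sp.issparse(counts) else counts, dtype=np.float64
    )
    labels = np.asarray(labels)
    factors = tmm_factors(counts)
    s = counts.sum(axis=1) * factors
    y = counts.T
    y = y[y.sum(axis=1) > 0]
    return estimate_common_dispersion(y, s, labels)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p, dtype=np.float64)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def nb_lrt(
    counts: np.ndarray,
    groups: np.ndarray,
    factors: Optional[np.ndarray] = None,
    genes: Optional[Sequence[str]] = None,
    alpha: Optional[float] = None,
) -> pd.DataFrame:
    """NB likelihood-ratio test of group A vs group B for every gene.

    ``counts`` is observations x genes raw counts; ``groups`` a length-n
    vector with exactly two distinct labels (the first in sorted order is
    group A, the numerator of the fold-change).  Effective library sizes
    are raw totals times ``factors`` (TMM factors computed here when not
    given).  ``alpha`` overrides the estimated common dispersion.
    """
    counts = np.asarray(
        counts.todense() if sp.issparse(counts) else counts, dtype=np.float64
    )
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.tolist()}")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if factors is None:
        factors = tmm_factors(counts)
    s = counts.sum(axis=1) * np.asarray(factors, dtype=np.float64)

    y = counts.T  # genes x observations
    n_genes = y.shape[0]
    nonzero = y.sum(axis=1) > 0
    yz = y[nonzero]
    mask_a = groups == labels[0]
    mask_b = groups == labels[1]

    if alpha is None:
        alpha = estimate_common_dispersion(yz, s, groups)

    lam_null = _fit_means(yz, s, alpha)
    lam_a = _fit_means(yz[:, mask_a], s[mask_a], alpha)
    lam_b = _fit_means(yz[:, mask_b], s[mask_b], alpha)
    ll_null = _nb_loglik(yz, lam_null[:, None] * s[None, :], alpha)
    ll_alt = _nb_loglik(
        yz[:, mask_a], lam_a[:, None] * s[mask_a][None, :], alpha
    ) + _nb_loglik(yz[:, mask_b], lam_b[:, None] * s[mask_b][None, :], alpha)
    stat = np.clip(2.0 * (ll_alt - ll_null), 0.0, None)
    p_nz = chi2.sf(stat, df=1)

    log2fc = np.zeros(n_genes)
    p_raw = np.ones(n_genes)
    p_adj = np.ones(n_genes)
    log2fc[nonzero] = np.log2(np.clip(lam_a, 1e-12, None)) - np.log2(
        np.clip(lam_b, 1e-12, None)
    )
    p_raw[nonzero] = p_nz
    p_adj[nonzero] = bh_adjust(p_nz)

    frac_a = (counts[mask_a] > 0).mean(axis=0)
    frac_b = (counts[mask_b] > 0).mean(axis=0)
    mean_scale = s.mean()
    mean_a = np.zeros(n_genes)
    mean_b = np.zeros(n_genes)
    mean_a[nonzero] = lam_a * mean_scale
    mean_b[nonzero] = lam_b * mean_scale

    idx = pd.Index(
        genes if genes is not None else [f"g{i}" for i in range(n_genes)], name="gene"
    )
    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "frac_A": frac_a,
            "frac_B": frac_b,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "all_zero": ~nonzero,
        },
        index=idx,
    ).assign(dispersion=alpha)


def de_between(
    data,
    labels: Sequence,
    group_a,
    group_b,
    alpha: Optional[float] = None,
) -> pd.DataFrame:
    """Differential expression between two cell/replicate groups.

    ``data`` is an AnnData (raw counts taken from ``layers["counts"]`` when
    present, else ``X``) or an observations x genes array; ``labels`` one
    group label per observation.  Group A is the fold-change numerator.
    Observations outside the two groups are ignored.
    """
    if isinstance(data, ad.AnnData):
        counts = data.layers.get("counts", data.X)
        counts = np.asarray(
            counts.todense() if sp.issparse(counts) else counts, dtype=np.float64
        )
        genes = list(data.var_names)
    else:
        counts = np.asarray(
            data.todense() if sp.issparse(data) else data, dtype=np.float64
        )
        genes = None
    labels = np.asarray(labels)
    if labels.shape[0] != counts.shape[0]:
        raise ValueError("labels must match the number of observations")
    sel = np.isin(labels, [group_a, group_b])
    counts = counts[sel]
    groups = np.where(labels[sel] == group_a, "A", "B")
    return nb_lrt(counts, groups, genes=genes, alpha=alpha)
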