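"""Synthetic single-cell and bulk RNA-seq data with planted ground truth.

The generator emulates the structure of a six-sample CRC liver-metastasis
CAF study: UMI counts are negative-binomial with ``Var = mu + alpha*mu^2``,
per-cell library sizes are log-normal multipliers on the mean, and marker
fold-changes are planted on the mean scale before library-size scaling so
that the differential-expression engine can recover them by its own
definition of fold-change.

The CAF dataset has a nested population structure (two main populations,
each split into two subpopulations); a companion flat three-population
"liver atlas" shares marker genes with the CAF populations so that origin
transfer is learnable; a cancer-cell matrix plus a ligand-receptor pair
table with planted biased / reliable / null pairs feeds the crosstalk
stage; and a small two-condition bulk experiment with planted fold-changes
feeds the silencing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

DEFAULT_TREE: Dict[str, Tuple[str, ...]] = {
    "ECM-CAF": ("CP-CAF", "CS-CAF"),
    "Ctr-CAF": ("Ctr-CAF-I", "Ctr-CAF-II"),
}

#: atlas population -> CAF population whose markers it shares (origin truth)
DEFAULT_ORIGIN_MAP: Dict[str, str] = {
    "VSMC-like": "Ctr-CAF-I",
    "HSC-like": "Ctr-CAF-II",
    "SAMes-like": "ECM-CAF",
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic CAF study.

    Defaults are the desk-scale study conditions: 2,000 genes, six samples
    of 300 cells, 30 planted markers per subpopulation and 20 per main
    population at 8-fold change, NB dispersion 0.3 and mild log-normal
    depth variation.
    """

    n_genes: int = 2000
    n_cells_per_sample: int = 300
    n_samples: int = 6
    population_tree: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TREE)
    )
    marker_plan: Optional[List[Tuple[str, str, float]]] = None
    libsize_lognormal: Tuple[float, float] = (0.0, 0.25)
    nb_dispersion: float = 0.3
    rare_gene_fraction: float = 0.15
    n_markers_per_sub: int = 30
    n_markers_per_main: int = 20
    marker_fold_change: float = 8.0
    n_atlas_private_markers: int = 20
    seed: int = 0

    # ------------------------------------------------------------------ #

    def gene_names(self) -> List[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def sample_names(self) -> List[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    @property
    def main_populations(self) -> List[str]:
        return list(self.population_tree)

    @property
    def sub_populations(self) -> List[str]:
        return [s for subs in self.population_tree.values() for s in subs]

    def main_of(self, sub: str) -> str:
        for main, subs in self.population_tree.items():
            if sub in subs or sub == main:
                return main
        raise KeyError(sub)

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.n_samples < 1 or self.n_genes < 1 or self.n_cells_per_sample < 1:
            raise ConfigurationError("counts must be positive")
        if not self.population_tree or any(
            len(subs) < 1 for subs in self.population_tree.values()
        ):
            raise ConfigurationError("population_tree must map mains to subpopulations")
        pops = set(self.main_populations) | set(self.sub_populations)
        genes = set(self.gene_names())
        for gene, pop, fc in self.resolved_marker_plan():
            if fc < 1:
                raise ConfigurationError(f"marker {gene}: fold_change {fc} < 1")
            if pop not in pops:
                raise ConfigurationError(f"marker {gene}: unknown population {pop!r}")
            if gene not in genes:
                raise ConfigurationError(f"marker gene {gene} outside gene universe")

    def resolved_marker_plan(self) -> List[Tuple[str, str, float]]:
        """The explicit marker plan, generating the default one on demand.

        The default plan assigns consecutive gene blocks: 30 markers to each
        subpopulation then 20 to each main population, all at 8-fold change.
        """
        if self.marker_plan is not None:
            return list(self.marker_plan)
        genes = self.gene_names()
        plan: List[Tuple[str, str, float]] = []
        i = 0
        for sub in self.sub_populations:
            for _ in range(self.n_markers_per_sub):
                plan.append((genes[i], sub, self.marker_fold_change))
                i += 1
        for main in self.main_populations:
            for _ in range(self.n_markers_per_main):
                plan.append((genes[i], main, self.marker_fold_change))
                i += 1
        return plan

    def _reserved_marker_slots(self) -> int:
        """Gene indices reserved for CAF plus atlas-private markers."""
        n_caf = (
            len(self.sub_populations) * self.n_markers_per_sub
            + len(self.main_populations) * self.n_markers_per_main
        )
        return n_caf + len(DEFAULT_ORIGIN_MAP) * self.n_atlas_private_markers


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    cell_labels: pd.DataFrame  # index barcode; columns sample, main, sub
    marker_table: pd.DataFrame  # columns gene, population, fold_change
    lr_truth: Optional[pd.DataFrame] = None
    bulk_de_genes: Optional[pd.Series] = None


# ---------------------------------------------------------------------- #
# gene baselines, shared between the CAF dataset and the reference atlas


def _gene_baselines(config: SimConfig) -> np.ndarray:
    """Per-gene mean UMI counts for an average-depth cell.

    A two-component log-normal mixture: most genes at moderate expression
    (median ~1.6 counts) plus a rare tail (median ~0.05) that exercises the
    1%-of-cells expression filter.  Marker slots are pinned to mean 1.0 so
    planted fold-changes land on genes detectable in most cells.  The draw
    is a pure function of the seed, so the CAF dataset and the atlas share
    identical baselines (their cells differ only by population effects).
    """
    rng = np.random.default_rng(config.seed * 2654435761 % (2**31) + 17)
    base = rng.lognormal(mean=0.5, sigma=0.8, size=config.n_genes)
    n_reserved = config._reserved_marker_slots()
    free = np.arange(n_reserved, config.n_genes)
    n_rare = int(round(config.rare_gene_fraction * config.n_genes))
    n_rare = min(n_rare, free.size)
    rare_idx = rng.choice(free, size=n_rare, replace=False)
    base[rare_idx] = rng.lognormal(mean=-3.0, sigma=1.5, size=n_rare)
    base[:n_reserved] = 1.0
    return base


def _fc_vector(
    config: SimConfig, population: str, plan: Sequence[Tuple[str, str, float]]
) -> np.ndarray:
    """Fold-change multiplier per gene for cells of one subpopulation."""
    gene_index = {g: i for i, g in enumerate(config.gene_names())}
    fc = np.ones(config.n_genes)
    main = config.main_of(population)
    for gene, pop, f in plan:
        if pop == population or pop == main:
            fc[gene_index[gene]] *= f
    return fc


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, Var = mu + alpha*mu^2) via the (n, p) parameterization."""
    n = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mu)
    return rng.negative_binomial(n, p)


def _counts_for_groups(
    rng: np.random.Generator,
    config: SimConfig,
    group_means: Dict[str, np.ndarray],
    groups: Sequence[str],
) -> Tuple[sp.csr_matrix, np.ndarray]:
    """Draw NB counts for an ordered cell list with per-cell library sizes."""
    meanlog, sdlog = config.libsize_lognormal
    n_cells = len(groups)
    libs = rng.lognormal(mean=meanlog, sigma=sdlog, size=n_cells)
    rows = []
    for c in range(n_cells):
        mu = group_means[groups[c]] * libs[c]
        rows.append(_nb_draw(rng, mu, config.nb_dispersion))
    X = sp.csr_matrix(np.vstack(rows).astype(np.int32))
    return X, libs


# ---------------------------------------------------------------------- #


def simulate_caf_dataset(config: SimConfig) -> Tuple[ad.AnnData, SimTruth]:
    """Generate the nested-population CAF dataset with planted markers.

    Each sample contains all four subpopulations in equal proportion.
    Returns a cells x genes AnnData of raw UMI counts (obs columns
    ``sample``, ``main``, ``sub``, ``fraction``) and the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    plan = config.resolved_marker_plan()
    base = _gene_baselines(config)
    subs = config.sub_populations
    pop_means = {s: base * _fc_vector(config, s, plan) for s in subs}

    barcodes, samples, sub_labels = [], [], []
    for sample in config.sample_names():
        n = config.n_cells_per_sample
        per = [n // len(subs)] * len(subs)
        for i in range(n - sum(per)):
            per[i] += 1
        labels = [s for s, k in zip(subs, per) for _ in range(k)]
        sub_labels.extend(labels)
        samples.extend([sample] * n)
        barcodes.extend(f"{sample}_C{i:04d}" for i in range(n))

    X, libs = _counts_for_groups(rng, config, pop_means, sub_labels)
    obs = pd.DataFrame(
        {
            "sample": samples,
            "sub": sub_labels,
            "main": [config.main_of(s) for s in sub_labels],
            "fraction": "TN",
            "libsize_factor": libs,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    var = pd.DataFrame(
        {"baseline_mean": base}, index=pd.Index(config.gene_names(), name="gene")
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    truth = SimTruth(
        cell_labels=obs[["sample", "main", "sub"]].copy(),
        marker_table=pd.DataFrame(plan, columns=["gene", "population", "fold_change"]),
    )
    return adata, truth


def simulate_reference_atlas(
    config: SimConfig,
    n_cells_per_pop: int = 500,
    shared_marker_fraction: float = 1.0,
    origin_map: Optional[Dict[str, str]] = None,
    seed: Optional[int] = None,
) -> Tuple[ad.AnnData, SimTruth]:
    """Generate the flat three-population mesenchymal reference atlas.

    Each atlas population carries a ``shared_marker_fraction`` of the marker
    genes of the CAF population it maps to (its planted origin) plus a
    private marker block, so origin transfer is learnable at fraction 1 and
    collapses to chance at fraction 0.
    """
    config.validate()
    if not 0 <= shared_marker_fraction <= 1:
        raise ConfigurationError("shared_marker_fraction must be in [0, 1]")
    origin_map = dict(DEFAULT_ORIGIN_MAP if origin_map is None else origin_map)
    rng = np.random.default_rng((seed if seed is not None else config.seed + 1) % 2**31)
    base = _gene_baselines(config)
    genes = config.gene_names()
    gene_index = {g: i for i, g in enumerate(genes)}
    plan = config.resolved_marker_plan()
    caf_markers: Dict[str, List[str]] = {}
    for gene, pop, _fc in plan:
        caf_markers.setdefault(pop, []).append(gene)

    n_caf_slots = (
        len(config.sub_populations) * config.n_markers_per_sub
        + len(config.main_populations) * config.n_markers_per_main
    )
    pop_means: Dict[str, np.ndarray] = {}
    marker_rows: List[Tuple[str, str, float]] = []
    for k, (atlas_pop, caf_pop) in enumerate(origin_map.items()):
        fc = np.ones(config.n_genes)
        shared: List[str] = []
        if caf_pop in config.population_tree:  # a main: its markers + its subs'
            shared += caf_markers.get(caf_pop, [])
            for sub in config.population_tree[caf_pop]:
                shared += caf_markers.get(sub, [])
        else:
            shared += caf_markers.get(caf_pop, [])
            shared += caf_markers.get(config.main_of(caf_pop), [])
        n_shared = int(round(shared_marker_fraction * len(shared)))
        shared = shared[:n_shared]
        lo = n_caf_slots + k * config.n_atlas_private_markers
        private = genes[lo : lo + config.n_atlas_private_markers]
        for g in shared + list(private):
            fc[gene_index[g]] *= config.marker_fold_change
            marker_rows.append((g, atlas_pop, config.marker_fold_change))
        pop_means[atlas_pop] = base * fc

    labels = [p for p in origin_map for _ in range(n_cells_per_pop)]
    X, libs = _counts_for_groups(rng, config, pop_means, labels)
    barcodes = [f"ATLAS_C{i:04d}" for i in range(len(labels))]
    obs = pd.DataFrame(
        {"population": labels, "libsize_factor": libs},
        index=pd.Index(barcodes, name="barcode"),
    )
    var = pd.DataFrame(
        {"baseline_mean": base}, index=pd.Index(genes, name="gene")
    )
    adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=var)
    truth = SimTruth(
        cell_labels=obs[["population"]].copy(),
        marker_table=pd.DataFrame(
            marker_rows, columns=["gene", "population", "fold_change"]
        ),
    )
    return adata, truth


def simulate_cancer_cells(
    config: SimConfig, seed: Optional[int] = None
) -> ad.AnnData:
    """Generate a flat cancer-cell matrix over the same gene universe."""
    config.validate()
    rng = np.random.default_rng((seed if seed is not None else config.seed + 2) % 2**31)
    base = _gene_baselines(config)
    pop_means = {"Cancer": base}
    labels = []
    samples = []
    for sample in config.sample_names():
        labels.extend(["Cancer"] * config.n_cells_per_sample)
        samples.extend([sample] * config.n_cells_per_sample)
    X, libs = _counts_for_groups(rng, config, pop_means, labels)
    barcodes = [f"{s}_E{i:04d}" for i, s in enumerate(samples)]
    obs = pd.DataFrame(
        {
            "sample": samples,
            "population": "Cancer",
            "fraction": "EPCAM+",
            "libsize_factor": libs,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    var = pd.DataFrame(
        {"baseline_mean": base}, index=pd.Index(config.gene_names(), name="gene")
    )
    return ad.AnnData(X=X, obs=obs, var=var)


def simulate_lr_truth(
    config: SimConfig,
    caf: ad.AnnData,
    caf_truth: SimTruth,
    cancer: ad.AnnData,
    n_biased: Tuple[int, int] = (10, 5),
    n_reliable: int = 10,
    n_null: int = 50,
    ligand_fc: int = 8,
    receptor_boost: int = 4,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, ad.AnnData, ad.AnnData]:
    """Plant a ligand-receptor pair table with known biased/reliable/null pairs.

    Ligand genes are drawn from low baseline expression and their counts in
    the source population (both main populations for "reliable" pairs) are
    redrawn from the negative binomial with the mean multiplied by
    ``ligand_fc`` — a generative boost that raises detection as well as
    magnitude, the way a genuinely population-specific ligand behaves — so
    biased pairs clear both the median-score and the ligand
    differential-expression gates while reliable pairs clear only the
    median gate.  Receptor genes come from the top of the baseline
    distribution and are likewise boosted in cancer cells so that
    receptor-side expression never limits a planted interaction.  Null
    pairs use untouched rare genes and stay below the score threshold.

    Returns (pair table, truth table, boosted CAF AnnData, boosted cancer
    AnnData); the inputs are not modified.
    """
    config.validate()
    if ligand_fc < 1 or int(ligand_fc) != ligand_fc:
        raise ConfigurationError("ligand_fc must be a positive integer factor")
    rng = np.random.default_rng((seed if seed is not None else config.seed + 3) % 2**31)
    mains = config.main_populations
    if len(mains) != 2:
        raise ConfigurationError("LR planting requires exactly two main populations")
    base = np.asarray(caf.var["baseline_mean"])
    reserved = config._reserved_marker_slots()
    free = np.arange(reserved, config.n_genes)
    order = free[np.argsort(base[free])]
    n_free = order.size
    # Bands chosen on the mean-count scale: planted ligands sit low enough
    # that the log-compressed score separates an 8-fold boost across the
    # 0.5 threshold; null-pair genes are rarer still and never score;
    # receptors come from the top decile so the receptor side never limits
    # a planted interaction.
    rare = order[base[order] < 0.05]
    low = order[(base[order] >= 0.08) & (base[order] <= 0.25)]
    high = order[int(n_free * 0.9) :]

    n_a, n_b = n_biased
    n_lig = n_a + n_b + n_reliable
    n_rec = n_lig + n_null
    if len(low) < n_lig or len(high) < n_lig or len(rare) < 2 * n_null:
        raise ConfigurationError("not enough free genes for the requested pairs")
    lig_idx = rng.choice(low, size=n_lig, replace=False)
    rec_idx = rng.choice(high, size=n_lig, replace=False)
    null_idx = rng.choice(rare, size=2 * n_null, replace=False)
    genes = caf.var_names.to_numpy()

    caf = caf.copy()
    cancer = cancer.copy()
    caf_X = np.asarray(sp.csr_matrix(caf.X).todense())
    cancer_X = np.asarray(sp.csr_matrix(cancer.X).todense())
    sub_of = caf.obs["main"].to_numpy()
    caf_libs = caf.obs["libsize_factor"].to_numpy()
    cancer_libs = cancer.obs["libsize_factor"].to_numpy()
    alpha = config.nb_dispersion

    def redraw(X, rows_mask, col, libs, factor):
        mu = base[col] * factor * libs[rows_mask]
        X[rows_mask, col] = _nb_draw(rng, mu, alpha)

    rows, truth_rows = [], []
    classes = [("biased", mains[0])] * n_a + [("biased", mains[1])] * n_b + [
        ("reliable", None)
    ] * n_reliable
    all_caf = np.ones(caf.n_obs, dtype=bool)
    all_cancer = np.ones(cancer.n_obs, dtype=bool)
    for j, (cls, source) in enumerate(classes):
        lg, rg = genes[lig_idx[j]], genes[rec_idx[j]]
        boosted = sub_of == source if source is not None else all_caf
        redraw(caf_X, boosted, lig_idx[j], caf_libs, ligand_fc)
        redraw(cancer_X, all_cancer, rec_idx[j], cancer_libs, receptor_boost)
        rows.append((lg, rg))
        truth_rows.append((lg, rg, source, "Cancer", cls))
    for j in range(n_null):
        lg, rg = genes[null_idx[2 * j]], genes[null_idx[2 * j + 1]]
        rows.append((lg, rg))
        truth_rows.append((lg, rg, None, "Cancer", "null"))

    pairs = pd.DataFrame(rows, columns=["ligand", "receptor"])
    lr_truth = pd.DataFrame(
        truth_rows,
        columns=["ligand", "receptor", "source_pop", "target_pop", "planted_class"],
    )
    caf.X = sp.csr_matrix(caf_X).astype(np.int32)
    cancer.X = sp.csr_matrix(cancer_X).astype(np.int32)
    return pairs, lr_truth, caf, cancer


def simulate_bulk_experiment(
    n_genes: int = 10000,
    n_de: int = 100,
    log2fc: float = 2.0,
    n_reps: int = 4,
    dispersion: float = 0.05,
    mean_lognormal: Tuple[float, float] = (5.0, 1.8),
    libsize_lognormal: Tuple[float, float] = (0.0, 0.1),
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Generate a two-condition bulk RNA-seq count table with planted DE genes.

    Emulates an siRNA-silencing experiment: ``n_reps`` knockdown replicates
    ("si") against ``n_reps`` non-target controls ("nt").  Half the planted
    genes go up by ``log2fc`` in the knockdown group, half down.  Returns a
    genes x samples integer DataFrame and a Series of planted signed log2
    fold-changes (si over nt) indexed by gene, zero for unperturbed genes.
    """
    if n_de < 0 or n_de > n_genes:
        raise ConfigurationError("n_de must be in [0, n_genes]")
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    if dispersion <= 0:
        raise ConfigurationError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"B{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(*mean_lognormal, size=n_genes)
    signs = np.zeros(n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs[de_idx[: n_de // 2]] = 1.0
    signs[de_idx[n_de // 2 :]] = -1.0
    truth = pd.Series(signs * log2fc, index=pd.Index(genes, name="gene"))

    cols = [f"si_{r + 1}" for r in range(n_reps)] + [
        f"nt_{r + 1}" for r in range(n_reps)
    ]
    libs = rng.lognormal(*libsize_lognormal, size=2 * n_reps)
    counts = np.empty((n_genes, 2 * n_reps), dtype=np.int64)
    for j, col in enumerate(cols):
        mu = base * libs[j]
        if col.startswith("si"):
            mu = mu * 2.0 ** truth.to_numpy()
        counts[:, j] = _nb_draw(rng, mu, dispersion)
    table = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=cols)
    return table, truth


def bulk_condition_labels(columns: Sequence[str]) -> pd.Series:
    """Condition labels ("si"/"nt") inferred from bulk column names."""
    return pd.Series(
        [c.split("_")[0] for c in columns], index=pd.Index(columns, name="sample")
    )
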