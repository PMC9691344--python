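# cafkit

Cancer-associated fibroblasts (CAFs) are the dominant stromal cell type of
colorectal-cancer liver metastases, and their heterogeneity — which
subpopulations exist, which liver cell types they derive from, and how
each subpopulation talks to cancer cells — shapes both prognosis and
therapeutic options.  `cafkit` is a reusable, tested implementation of a
complete transcriptomic pipeline for this question, aimed at computational
biologists who want each stage as a library function rather than a frozen
analysis script:

* **Single-cell QC and clustering** — per-sample top-UMI doublet removal,
  a detected-gene floor, total-count normalization with `log2(1 + x)`,
  CV-based variable-gene selection, and Ward hierarchical clustering into
  two main CAF populations nested over four subpopulations.
* **Consensus marker signatures** — a gene enters a subpopulation
  signature only if it is expressed in ≥ 20% of the cluster's cells and
  shows FC ≥ 2 at adjusted P ≤ 1% against the sibling clusters pooled
  *and* against each sibling individually (top 30 by fold-change; top 16
  for the reference-atlas rule), with hypergeometric overlap tests between
  signatures.
* **Differential expression** — one negative-binomial engine for
  single-cell and bulk contrasts: TMM library normalization, a common
  dispersion by Cox–Reid adjusted profile likelihood, likelihood-ratio
  tests against chi-square(1), Benjamini–Hochberg correction.
* **CAF origin classification** — random-forest / kNN (k = 100) / linear
  SVM engines trained on a labeled liver mesenchymal atlas, stratified
  90/10 cross-validation repeated 20 times, per-population assignment
  tables, and multinomial composition tests.
* **Ligand–receptor crosstalk** — per-sample scores
  `sqrt(l·r) / (mu + sqrt(l·r))`, reliability on the median over samples
  (strictly > 0.5), and selection of population-biased interactions
  (Δmedian > 0.1 plus a differential-expression gate on the featured
  ligand).
* **Bulk silencing stage** — two-condition DE at adjusted p < 0.01 and
  |FC| > 2, per-gene z-scores of log2-transformed TMM-normalized counts,
  and hypergeometric GO-term enrichment over a user-supplied GMT.
* **Synthetic data** — negative-binomial generators that plant a known
  2-main/4-sub population structure, marker fold-changes, a 3-population
  reference atlas, biased/reliable/null ligand-receptor pairs, and a bulk
  experiment with known perturbed genes, so every stage is testable
  without any download.

See `docs/methods.md` for the model details, parameter defaults, and the
limits of what the synthetic data emulates.

## Worked example

Simulate the default six-sample CAF study, run QC and clustering, and
derive the consensus signatures:

```python
from sklearn.metrics import adjusted_rand_score
from cafkit.simulate import SimConfig, simulate_caf_dataset
from cafkit.preprocess import preprocess
from cafkit.cluster import ward_cluster
from cafkit.signatures import derive_nested_signatures

config = SimConfig(seed=1)                    # 2,000 genes, 6 x 300 cells
adata, truth = simulate_caf_dataset(config)
norm, doublets, var_genes = preprocess(adata)
print(f"{norm.n_obs} cells pass QC; {len(doublets)} doublets removed")

tree = ward_cluster(norm[:, var_genes].X)
print("subpopulation ARI:",
      round(adjusted_rand_score(norm.obs["sub"], tree.cuts[4]), 3))

signatures = derive_nested_signatures(norm)
sig = signatures["CP-CAF"]
print(len(sig), "genes; top:", sig.genes[:3])
```

This prints:

```
1741 cells pass QC; 6 doublets removed
subpopulation ARI: 1.0
30 genes; top: ['G0016', 'G0007', 'G0023']
```

1,741 of 1,800 simulated cells survive the 0.05% doublet cut and the
1,000-detected-gene floor; the Ward k = 4 cut recovers the four planted
subpopulations exactly (adjusted Rand index 1.0); and the collagen-
producing-CAF signature contains 30 genes — all 30 planted CP-CAF markers
— ordered by their fitted fold-change (≈ 8-fold, as planted).

The same stages are exposed on the command line via the `cafkit`
entry point (`cafkit simulate`, `cafkit preprocess`, `cafkit cluster`,
`cafkit de`, `cafkit bulk`, `cafkit bulk-sim`).

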