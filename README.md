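# tilbkit

Analysis toolkit for tumor-infiltrating B cells (TIL-B) in single-cell
transcriptomics, bulk-cohort survival data, and multiplexed tissue images.

Tumor-infiltrating B cells organize into tertiary lymphoid structures (TLS),
and TLS that contain an active germinal center (GC) are associated with
better outcomes in head and neck cancer. Studying them computationally
requires a set of connected but unusual analyses that standard single-cell
toolkits do not cover as a unit:

* **semi-supervised lineage identification** — derive a ~20-gene "core
  program" per immune lineage from a labeled reference, score every cell of
  a new dataset with a one-sided Wilcoxon rank-sum on its per-cell
  log-fold-changes, and label clusters by majority vote;
* **variance-inflation-corrected gene-set tests** — a rank-sum test on
  cluster log-fold-changes whose null variance is inflated by
  `VIF = 1 + (m−1)·ρ̄` (ρ̄ = mean pairwise inter-gene correlation) so that
  co-expressed gene sets do not produce spurious enrichment;
* **cluster-by-group enrichment ratios** — patient-normalized
  observed/expected cell frequencies per cluster;
* **cyclical pseudotime** — GC B cells toggle between dark and light zones,
  so their state lies on a closed loop: cells are embedded in a diffusion
  map, the most circular diffusion-component pair is selected, a closed
  principal curve is fitted through the cluster ring, and each cell receives
  a phase on [0, 1); gene dynamics along the phase are fitted with periodic
  local regression and clustered into expression "waves";
* **per-sample KS enrichment and survival stratification** — each patient's
  bulk transcriptome gets a signed Kolmogorov–Smirnov enrichment score for a
  cell-population signature; patients are split at the score cutpoint
  maximizing the log-rank statistic (with an honesty-preserving
  permutation-adjusted p) and compared by Cox proportional hazards;
* **Delaunay neighborhood odds** — in segmented tissue images, cells
  sharing a Delaunay edge are neighbors, and cell-type interactions are
  summarized as edge-level odds ratios with label-permutation significance.

Every stage ships with a synthetic-data generator that reproduces the
statistical structure the stage assumes (lineage programs, phase-shifted
von Mises expression waves, hazard-coupled cohorts, TLS-like point
patterns), so the whole pipeline is testable without any data download.

## Worked example: cyclical pseudotime of a germinal-center cycle

```python
import numpy as np
import tilbkit as tk

# simulate a 600-cell germinal-center cycle with three expression waves
m, truth = tk.gen_gc_cycle(n_cells=600, n_genes=500, n_programs=3,
                           kappa=2.0, seed=5)

tk.normalize_log(m)
hvg = tk.select_hvg(m, n_hvg=200)
covars = tk.compute_technical_covariates(m)
pca = tk.embed_pca(m, hvg, covars, n_pc=20)
dmap = tk.diffusion_map(pca, n_dc=10, kernel_k=30)
clusters = tk.cluster_graph(dmap, k_neighbors=20, seed=5)

pair, circ = tk.select_circular_components(dmap)
cpt = tk.fit_cyclical_pseudotime(dmap, clusters, pair)

genes = [g for prog in truth.programs.values() for g in prog]
dyn = tk.fit_gene_dynamics(m, cpt, genes)
waves = tk.cluster_gene_waves(dyn, k="auto")
```

Output:

```
most circular component pair: DC1/DC2 (circularity 0.77)
phase recovery (circular correlation): 0.969
expression waves found: 3
  wave 1: 20 genes, median peak phase 0.03
  wave 2: 20 genes, median peak phase 0.38
  wave 3: 20 genes, median peak phase 0.72
```

The three recovered waves are the three generated programs: each peaks near
its generating phase center (0, 1/3, 2/3), exactly the dark-zone /
transitional / light-zone wave structure the cyclical model is built to
expose, and the inferred per-cell phase matches the simulated phase with
circular correlation 0.97.

A command-line interface mirrors the library
(`tilbkit simulate|preprocess|classify|gsea|enrich|pseudotime|survival|spatial`);
each run writes CSV outputs plus a JSON manifest with parameters and seed.

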