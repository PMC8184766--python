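# Methods

This note documents the models and procedures implemented in `tilbkit`,
the defaults chosen where the design was genuinely open, and what the
synthetic generators do and do not emulate.

## Synthetic data model

All four generators are pure functions of their parameters and a seed.

**UMI counts.** Counts are negative binomial parameterized by (mean μ,
dispersion φ) with variance μ + μ²/φ, sampled as a gamma–Poisson mixture;
`dispersion=inf` degenerates to Poisson. Baseline gene means are
log-normal(meanlog −1, sdlog 1) rescaled so the expected cell depth is
~3,000 UMIs — a plausible droplet-assay depth that mimics no particular
dataset. Default φ = 2, a typical droplet-data value. The generators do
**not** emulate batch effects, doublets, or ambient RNA, so passing
recovery tests demonstrates correctness of the inference machinery on
clean data, not robustness to those artifacts.

**Lineages** (`gen_lineage_counts`): each of L lineages owns a disjoint
program of `program_size` (default 20) genes whose means are multiplied by
`fold` in cells of that lineage.

**Germinal-center cycle** (`gen_gc_cycle`): cell phases θ ~ Uniform[0, 1);
program p's genes are scaled by the von Mises-shaped wave
exp(κ·cos(2π(θ − φ_p)))/I₀(κ), whose circular mean is 1, with program
centers φ_p equally spaced. A von Mises wave rather than a sinusoid makes
wave sharpness (hence program overlap) a single tunable κ. Program gene
baselines are floored at the median baseline so waves ride on expressed
genes rather than drop-out-dominated ones.

**Survival cohort** (`gen_bulk_survival`): latent score s ~ N(0, 1);
signature-gene expression = baseline + coupling·s + N(0, 1) noise; event
times exponential with rate λ₀·exp(β·s) (exponential baseline hazard —
Cox is semiparametric, so the baseline form is immaterial to estimation).
Censoring is an independent exponential competing risk whose rate is
solved (Brent's method) so the marginal expected censored fraction equals
`censor_frac`; this closed-form calibration is why an exponential rather
than uniform censor law is used — the contract being matched is the
censored fraction, which the empirical check confirms to within
Monte-Carlo error.

**Spatial patterns** (`gen_spatial_map`): `mixed` (uniform positions,
i.i.d. labels — the null), `segregated` (one Gaussian blob per type,
centers ≥ 6 blob SDs apart), `tls_gc` (central B-cell disc of radius 100,
CD4 ring 120–200, sparse others — an idealized TLS with germinal center),
`tls_nogc` (B cells dispersed among CD8/Treg). Units are arbitrary.

## Preprocessing

Normalization is per-cell library-size scaling to 10,000 counts followed
by ln(x + 1). HVG selection ranks genes by dispersion (variance/mean of
lognorm) z-scored within 20 equal-occupancy mean bins; ties break by gene
id so the ranking is fully deterministic. Before PCA, each HVG is
regressed on three technical covariates (genes detected, mitochondrial
fraction, ribosomal fraction), z-scored, and clipped at ±10 SD (outlier
robustness; the clip is a parameter). Constant covariates are dropped, so
with all-zero covariates the regression degenerates to centering. Default
`n_pc=20`: the number of informative components is a per-dataset judgment
call, so the package uses an explicit, overridable default and reports the
variance spectrum for elbow inspection.

Clustering builds a k-nearest-neighbor graph (k = 20) reweighted by
Jaccard overlap of neighbor sets (shared-nearest-neighbor weights), then
maximizes modularity via the Leiden algorithm (RBConfiguration null model)
at the given resolution with an explicit seed. The label contract —
consecutive integers from 1, ordered by descending size — is enforced on
top of the backend so downstream references are stable.

The diffusion map uses a Gaussian kernel with per-cell adaptive bandwidth
(distance to the `kernel_k`-th neighbor, default 30) and density
correction (the kernel is divided by the outer product of its row sums
before row-normalization), the standard construction for uneven sampling
densities. Eigenvectors come from the symmetric conjugate of the
transition operator; the trivial constant eigenvector is dropped and
components are scaled by their eigenvalues. Coincident points (zero
bandwidth) raise an error suggesting jitter. The canonical trajectory
path runs diffusion on the PCA embedding: PCA denoising first measurably
improves phase recovery on noisy count data.

## Cell-type identification

Per-cell scoring computes `lfc_g = lognorm[c, g] − mean_c' lognorm[c', g]`
— the dataset mean is the reference because it is the simplest reference
making per-cell fold-changes well defined — and tests each core program's
fold-changes against the rest with a one-sided (greater) Wilcoxon rank-sum:
enrichment means program genes rank high. The normal approximation uses
tie correction and a 0.5 continuity correction; for small problems
(program ≤ 10 genes and ≤ 25 genes total) an exact tie-aware dynamic
program over doubled midranks reproduces exhaustive rank-placement
enumeration at polynomial cost. Assignment takes the smallest p, breaking
ties by larger standardized statistic, then program name. `score_cells`
accepts raw-count matrices and builds the lognorm layer on the fly with
its `pseudo` pseudocount; matrices that already carry lognorm are used
as-is.

The normal approximation is accurate to |Δp| ≤ 0.02 against enumeration
for instances with at least 9 distinct genes (worst case over all rank
configurations); below that the worst-case gap grows (0.044 at N = 4),
which is exactly why exact mode is the default for every instance up to
25 genes.

## Gene-set testing with variance inflation

For set S of size m among N genes ranked by a cluster's log-fold-change,
the rank-sum U has null mean m(N+1)/2 and variance m(N−m)(N+1)/12 —
*if* the member genes are independent. Co-expression breaks that, so the
variance is multiplied by `VIF = 1 + (m−1)·ρ̄`, with ρ̄ the mean pairwise
Pearson correlation of the member genes across the tested cluster's cells
(the cells actually pooled into the statistic), floored at 0. The exact
inflation formula is a design decision: it is the standard inter-gene
correlation correction for set-level mean statistics. Null simulation at
within-set correlation 0.3 puts the corrected test near nominal level
(~0.04 at α = 0.05 over 1,000 replicates) while the uncorrected test
rejects ~0.3.

Enrichment ratios use patient-normalized frequencies
(observed = cells/patients per group) against an even-allocation
expectation; per-cluster ANOVA and contrast rank-sum tests operate on
**per-sample** frequencies, because patients, not cells, are the
experimental unit.

## Pseudotime

*Linear*: a minimum spanning tree over cluster centroids in diffusion
space; the unique tree path from start to end cluster defines a polyline;
cells of path clusters are projected orthogonally onto it and pseudotime
is arc length scaled to [0, 1] (off-path cells: NaN). This is a minimal
self-contained contract for a tree-path trajectory, not a full
simultaneous principal-curves implementation.

*Cyclical*: the component pair is chosen by a circularity score
1 − CV(radius) about the coordinate-wise median (an isotropic 2D Gaussian
scores ≈ 0.48; ≥ 0.7 is documented as confident), with manual override.
Cluster centroids in the chosen plane are ordered by angle about their
barycenter; initial phases are those angles; then 10 rounds of periodic
local-linear smoothing of each coordinate against phase (data replicated
at phase ± 1 to enforce wrap-around) alternate with re-projection of cells
onto the smoothed closed polyline, renormalizing arc length to [0, 1).
Two numerical details matter: (i) local regression evaluated on a fine
grid ripples at the data sampling frequency, and nearest-point projection
amplifies that ripple into phase jitter, so the evaluated curve is passed
through a circular moving average two data-spacings wide; (ii) the final
iteration uses a 4,096-point grid so chord-versus-arc discretization is
negligible (a noiseless circle is recovered with circular correlation
1 − 10⁻⁹). Phase origin is fixed at the lowest-numbered cluster's centroid
and orientation is chosen so cluster labels increase around the ring where
possible; since origin and orientation remain conventions, recovery is
always scored after optimal rotation/reflection alignment
(`align_phases`), and correlation uses the pairwise Fisher–Lee form, which
needs no mean direction and is therefore well defined for uniform phases.

Gene dynamics are LOESS-style local-linear fits of z-scored expression on
pseudotime (span 0.3, 100-point grid; cyclical fits replicate data at
phase ± 1, making fit(0) = fit(1⁻) by construction). Wave clustering uses
1 − Pearson correlation between fitted curves, average linkage, and when
k = "auto" the cut maximizing mean silhouette over k ∈ 2..6; wave labels
are ordered by (circular) mean peak phase. Anchor analysis ranks genes by
curve correlation with a chosen anchor gene, positive association only.

## Survival

The per-patient signed KS statistic ranks genes by expression (ties by
gene id for determinism) and takes the extremal ECDF difference between
signature and background genes; the sign comes from the first extremum of
the difference path, which makes swap-with-complement antisymmetry exact
even when the positive and negative excursions tie. A signed statistic is
required at all: stratifying "high versus low" needs an orientation that
an unsigned D cannot provide. The statistic is rank-based by construction,
hence invariant to any strictly monotone per-patient transform.

Cutpoint optimization scans midpoints between consecutive unique scores
(each side keeping ≥ `min_frac` of patients, default 0.1) and maximizes
the log-rank chi-square, ties to the smaller cutpoint. This "cutp"-style
procedure is anti-conservative by construction — the maximum of many
correlated tests — so the nominal p is co-reported with a permutation-
adjusted p (scores shuffled, optimization repeated, default 200 rounds).

The Cox model for the resulting binary split is fitted by Newton iteration
on the Breslow partial likelihood (a one-parameter problem with
closed-form score and information); the CI uses the observed information,
monotone likelihood (all events on one side) is flagged with an unbounded
CI, and the log-rank test is computed independently of the fit. The
Newton optimum matches a brute-force likelihood grid search to < 10⁻⁴ and,
on tie-free data, the Efron-based fit of an independent survival library
to < 10⁻⁵.

## Spatial neighborhoods

Delaunay edges (SciPy/Qhull) define the neighbor relation; degenerate
inputs (collinear sets, duplicate points) raise with a jitter suggestion.
An optional `max_edge` prune is available but off by default because edge
lengths are in data units whose biological meaning (contact range) is
dataset-dependent. Each undirected edge contributes both ordered endpoint
pairs; for ordered types (A, B) the 2×2 table over (first = A) ×
(second = B) yields an odds ratio, Haldane-corrected (+0.5 everywhere,
flagged) when a cell is zero. This aggregate construction makes
OR(A, B) = OR(B, A) exact. Significance is a two-sided label-permutation
test on |log OR| over the fixed graph (add-one empirical p, BH across
pairs) — the paper-level odds output says nothing about its null, so the
permutation null is the package's explicit choice.

## Problem sizes in tests

Recovery tests run at the generators' study-like conditions: 5 × 300
cells × 2,000 genes for the classifier, 600 cells × 3 programs at κ = 2
for the cycle, n = 300 patients × 50 replicates for stratification power,
1,000 null replicates for GSEA calibration, and 100 random ≤ 12-point
configurations against the O(n⁴) triangulation oracle. These sizes give
each check stable Monte-Carlo behavior while keeping the full suite fast.

## Known limitations

* The generators omit batch structure, doublets, ambient contamination,
  and spatial segmentation noise; recovery results bound method behavior
  on clean data only.
* Linear pseudotime handles a single path, not branching trajectories.
* The Cox implementation covers the single binary covariate the
  stratification workflow needs; multivariate models should use a
  dedicated survival library.
* Cutpoint stratification's nominal log-rank p remains biased even though
  a permutation-adjusted p is co-reported; downstream users should quote
  the adjusted value.
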