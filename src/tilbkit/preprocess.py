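"""Single-cell preprocessing: normalization, HVG selection, covariate-regressed
PCA, shared-neighbor graph clustering, and diffusion maps.

The workflow mirrors the standard droplet scRNA-seq recipe: library-size
normalization with log transform, dispersion-based highly-variable-gene
selection, per-gene regression of technical covariates followed by scaling
and clipping, PCA, modularity clustering on a shared-nearest-neighbor graph,
and a density-corrected diffusion-map embedding for trajectory work.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors

from .io_config import ExpressionMatrix


@dataclasses.dataclass
class EmbeddingResult:
    """Low-dimensional cell embedding; rows align with ``cell_ids``."""

    kind: str                 # "pca" or "diffusion"
    coordinates: np.ndarray   # cells x d
    spectrum: np.ndarray      # d values, nonincreasing
    cell_ids: list

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.coordinates.shape[1] < 2:
            raise ValueError("embedding needs >= 2 components")
        if np.any(np.diff(self.spectrum) > 1e-12):
            raise ValueError("spectrum must be nonincreasing")


@dataclasses.dataclass
class TechnicalCovariates:
    """Per-cell technical nuisance variables regressed out before PCA."""

    genes_detected: np.ndarray
    frac_mito: np.ndarray
    frac_ribo: np.ndarray

    def design(self):
        return np.column_stack([self.genes_detected, self.frac_mito,
                                self.frac_ribo]).astype(float)


def compute_technical_covariates(m: ExpressionMatrix,
                                 mito_prefixes=("MT-",),
                                 ribo_prefixes=("RPS", "RPL")) -> TechnicalCovariates:
    """Genes detected plus mitochondrial/ribosomal count fractions per cell."""
    totals = m.counts.sum(axis=1).astype(float)
    totals[totals == 0] = 1.0
    mito = np.array([g.startswith(tuple(mito_prefixes)) for g in m.gene_ids])
    ribo = np.array([g.startswith(tuple(ribo_prefixes)) for g in m.gene_ids])
    return TechnicalCovariates(
        genes_detected=(m.counts > 0).sum(axis=1).astype(float),
        frac_mito=m.counts[:, mito].sum(axis=1) / totals,
        frac_ribo=m.counts[:, ribo].sum(axis=1) / totals,
    )


def normalize_log(m: ExpressionMatrix, scale_total: float = 10000.0,
                  pseudocount: float = 1.0) -> ExpressionMatrix:
    """Library-size normalize and log transform.

    ``lognorm[c, g] = ln(counts[c, g] / total_c * scale_total + pseudocount)``.
    Raw counts are left untouched.  Cells with zero total count are rejected.
    """
    totals = m.counts.sum(axis=1).astype(float)
    if np.any(totals == 0):
        bad = [m.cell_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"cells with zero depth cannot be normalized: {bad[:10]}")
    m.lognorm = np.log(m.counts / totals[:, None] * scale_total + pseudocount)
    return m


def select_hvg(m: ExpressionMatrix, n_hvg: int = 2000, n_bins: int = 20) -> list:
    """Top highly-variable genes by binned standardized dispersion.

    Genes are ranked by dispersion (variance/mean of lognorm) z-scored within
    ``n_bins`` equal-occupancy mean-expression bins; ties break by gene id.
    """
    if m.lognorm is None:
        raise ValueError("run normalize_log first")
    if n_hvg > m.n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds {m.n_genes} genes")
    mean = m.lognorm.mean(axis=0)
    var = m.lognorm.var(axis=0, ddof=1) if m.n_cells > 1 else np.zeros(m.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # equal-occupancy bins on mean expression
    order = np.argsort(mean, kind="stable")
    bins = np.empty(m.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(m.n_genes) * n_bins) // max(m.n_genes, 1), n_bins - 1
    )
    z = np.zeros(m.n_genes)
    for b in np.unique(bins):
        mask = bins == b
        mu, sd = disp[mask].mean(), disp[mask].std(ddof=0)
        z[mask] = (disp[mask] - mu) / sd if sd > 0 else 0.0
    ranking = sorted(range(m.n_genes), key=lambda j: (-z[j], m.gene_ids[j]))
    return [m.gene_ids[j] for j in ranking[:n_hvg]]


def embed_pca(m: ExpressionMatrix, hvg, covars: TechnicalCovariates,
              n_pc: int = 20, clip: float = 10.0) -> EmbeddingResult:
    """Covariate-regressed, scaled, clipped PCA on the HVG submatrix.

    Per HVG the lognorm values are replaced by residuals of a linear
    regression on the technical covariates, z-scored, clipped at ``clip``
    standard deviations, then decomposed by PCA.  The spectrum holds the
    per-component explained variance.
    """
    if m.lognorm is None:
        raise ValueError("run normalize_log first")
    idx = m.gene_index(hvg)
    if n_pc >= min(m.n_cells, len(idx)):
        raise ValueError(f"n_pc={n_pc} must be < min(n_cells, n_hvg)")
    y = m.lognorm[:, idx]
    design = np.column_stack([np.ones(m.n_cells), covars.design()])
    # drop constant covariate columns; lstsq handles the rest
    keep = [0] + [j for j in range(1, design.shape[1])
                  if np.ptp(design[:, j]) > 0]
    design = design[:, keep]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sd = resid.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    scaled = np.clip(resid / sd, -clip, clip)
    scaled = scaled - scaled.mean(axis=0)  # clipping can shift the center
    u, s, vt = np.linalg.svd(scaled, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = (u * s)[:, :n_pc] * flip[:n_pc]
    explained = (s ** 2 / max(m.n_cells - 1, 1))[:n_pc]
    return EmbeddingResult("pca", coords, explained, list(m.cell_ids))


def cluster_graph(e: EmbeddingResult, k_neighbors: int = 20,
                  resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Shared-nearest-neighbor modularity clustering of an embedding.

    A kNN graph (Euclidean) is reweighted by Jaccard overlap of neighbor
    sets, then partitioned by seeded modularity maximization at the given
    resolution.  Labels are consecutive integers from 1 ordered by
    descending cluster size.
    """
    import igraph
    import leidenalg

    x = e.coordinates
    n = x.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x)
    _, nbr = nn.kneighbors(x)
    neighbor_sets = [set(row) for row in nbr]  # includes self
    edges, weights = [], []
    for i in range(n):
        for j in nbr[i][1:]:
            j = int(j)
            if j <= i and i in neighbor_sets[j]:
                continue  # already added from j's list
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w > 0:
                edges.append((min(i, j), max(i, j)))
                weights.append(w)
    # de-duplicate reciprocal edges
    uniq = {}
    for (a, b), w in zip(edges, weights):
        uniq[(a, b)] = w
    g = igraph.Graph(n=n, edges=list(uniq), edge_attrs={"weight": list(uniq.values())})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=int(seed),
    )
    raw = np.asarray(part.membership)
    # relabel 1..K by descending size, ties by original label
    labels_sorted = sorted(np.unique(raw), key=lambda l: (-(raw == l).sum(), l))
    remap = {old: new + 1 for new, old in enumerate(labels_sorted)}
    return np.array([remap[l] for l in raw], dtype=int)


def diffusion_map(data, n_dc: int = 10, kernel_k: int = 30) -> EmbeddingResult:
    """Density-corrected diffusion-map embedding.

    Gaussian kernel with per-cell adaptive bandwidth (distance to the
    ``kernel_k``-th neighbor), divided by the outer product of its row sums
    (density correction), row-normalized to a transition operator, and
    eigendecomposed.  The trivial constant eigenvector is dropped; the
    coordinates are the next ``n_dc`` eigenvectors scaled by their
    eigenvalues.
    """
    if isinstance(data, EmbeddingResult):
        x, cell_ids = data.coordinates, data.cell_ids
    elif isinstance(data, ExpressionMatrix):
        if data.lognorm is None:
            raise ValueError("run normalize_log first")
        x, cell_ids = data.lognorm, list(data.cell_ids)
    else:
        x = np.asarray(data, dtype=float)
        cell_ids = [str(i) for i in range(x.shape[0])]
    n = x.shape[0]
    if n < kernel_k + 2:
        raise ValueError(f"need >= kernel_k+2 = {kernel_k + 2} cells, got {n}")
    d = squareform(pdist(x))
    sigma = np.sort(d, axis=1)[:, kernel_k]
    if np.any(sigma == 0):
        raise ValueError(
            "zero adaptive bandwidth (coincident points); jitter the input"
        )
    k = np.exp(-(d ** 2) / np.outer(sigma, sigma))
    q = k.sum(axis=1)
    w = k / np.outer(q, q)  # density correction
    dsum = w.sum(axis=1)
    # symmetric conjugate of the row-normalized operator
    s = w / np.sqrt(np.outer(dsum, dsum))
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite kernel; jitter coincident points")
    vals, vecs = eigh(s)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    psi = vecs / np.sqrt(dsum)[:, None]
    # drop trivial (constant) eigenvector, keep the next n_dc
    lam = vals[1:n_dc + 1]
    comp = psi[:, 1:n_dc + 1]
    # unit-normalize then scale by eigenvalue; deterministic sign
    comp = comp / np.linalg.norm(comp, axis=0)
    flip = np.sign(comp[np.abs(comp).argmax(axis=0), np.arange(comp.shape[1])])
    flip[flip == 0] = 1.0
    coords = comp * flip * lam
    return EmbeddingResult("diffusion", coords, lam, cell_ids)
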