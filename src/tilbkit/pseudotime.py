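"""Linear and cyclical pseudotime inference with gene-dynamics wave clustering.

Germinal-center B cells toggle between dark-zone proliferation and
light-zone selection, so their transcriptional state lies on a closed loop
rather than a line.  This module provides both regimes:

* a linear trajectory (naive -> germinal center) as a minimum-spanning-tree
  path over cluster centroids in diffusion space, with cells projected onto
  the resulting polyline;
* a cyclical phase on [0, 1): clusters are ordered angularly around their
  barycenter in a chosen diffusion-component plane, a closed principal
  curve is iteratively smoothed through the cells, and each cell's phase is
  its arc-length position on the curve.

Gene expression is then fitted against pseudotime by local (LOESS-style)
regression — made seamless on the circle by replicating the data at
phase +/- 1 — and the fitted curves are clustered by correlation into
expression "waves".
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import silhouette_score

from .io_config import ExpressionMatrix
from .preprocess import EmbeddingResult

CONFIDENT_CIRCULARITY = 0.7


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LinearPseudotime:
    t: np.ndarray               # per-cell pseudotime in [0, 1]; NaN off-path
    path: list                  # ordered cluster sequence start..end
    curve: np.ndarray           # polyline vertices in embedding space
    cell_ids: list


@dataclasses.dataclass
class CyclicalPseudotime:
    phase: np.ndarray           # per-cell phase in [0, 1)
    pair: tuple                 # chosen component indices (i, j)
    ring: list                  # cyclic cluster order starting at the origin
    curve: np.ndarray           # closed polyline, first point == last point
    convention: dict            # orientation + origin record
    cell_ids: list


@dataclasses.dataclass
class GeneDynamics:
    genes: list
    grid: np.ndarray            # uniform pseudotime grid
    curves: np.ndarray          # genes x grid fitted scaled expression
    amplitude: np.ndarray
    peak_phase: np.ndarray
    cyclical: bool
    wave_cluster: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Circular helpers
# ---------------------------------------------------------------------------

def circular_correlation(a, b):
    """Fisher-Lee circular correlation of two phase vectors on [0, 1).

    The pairwise form sum_{i<j} sin(a_i - a_j) sin(b_i - b_j), normalized;
    it needs no mean direction (well-defined even for uniform phases) and
    equals +/-1 exactly when b = +/-a + c on the circle.
    """
    x = 2 * np.pi * np.asarray(a, dtype=float)
    y = 2 * np.pi * np.asarray(b, dtype=float)
    dx = np.sin(x[:, None] - x[None, :])
    dy = np.sin(y[:, None] - y[None, :])
    num = np.sum(dx * dy)
    denom = np.sqrt(np.sum(dx ** 2) * np.sum(dy ** 2))
    if denom == 0:
        return 0.0
    return float(num / denom)


def align_phases(est, truth):
    """Rotate (and reflect if needed) estimated phases onto true phases.

    Orientation and origin of a cyclical pseudotime are conventions;
    recovery is judged after the optimal rotation/reflection.  Returns
    ``(aligned, reflected)``.
    """
    est = np.asarray(est, dtype=float) % 1.0
    truth = np.asarray(truth, dtype=float) % 1.0
    best, best_err = est, np.inf
    reflected = False
    for sign in (1.0, -1.0):
        cand = (sign * est) % 1.0
        delta = 2 * np.pi * (truth - cand)
        offset = np.arctan2(np.sin(delta).mean(), np.cos(delta).mean()) / (2 * np.pi)
        aligned = (cand + offset) % 1.0
        err = np.mean(np.minimum(np.abs(aligned - truth),
                                 1 - np.abs(aligned - truth)) ** 2)
        if err < best_err:
            best, best_err, reflected = aligned, err, sign < 0
    return best, reflected


# ---------------------------------------------------------------------------
# Linear pseudotime
# ---------------------------------------------------------------------------

def fit_linear_pseudotime(e: EmbeddingResult, clusters, start, end) -> LinearPseudotime:
    """Pseudotime along the MST path of cluster centroids from start to end.

    Cells of path clusters are projected orthogonally onto the centroid
    polyline; t is arc length from the start centroid scaled to [0, 1].
    Cells off the path get NaN.
    """
    if start == end:
        raise ValueError("start and end clusters must differ")
    clusters = np.asarray(clusters)
    uniq = sorted(pd.unique(clusters), key=str)
    for k in (start, end):
        if k not in uniq:
            raise ValueError(f"cluster {k!r} not present")
    centroids = np.array([e.coordinates[clusters == k].mean(axis=0)
                          for k in uniq])
    dist = squareform(pdist(centroids))
    mst = minimum_spanning_tree(dist).toarray()
    adj = (mst > 0) | (mst.T > 0)
    path_idx = _tree_path(adj, uniq.index(start), uniq.index(end))
    if path_idx is None:
        raise ValueError("start and end are in disjoint components")
    path = [uniq[i] for i in path_idx]
    curve = centroids[path_idx]
    on_path = np.isin(clusters, path)
    t = np.full(len(clusters), np.nan)
    t[on_path] = _project_polyline(e.coordinates[on_path], curve, closed=False)
    span = np.nanmax(t) if np.nanmax(t) > 0 else 1.0
    t = t / span
    return LinearPseudotime(t=t, path=path, curve=curve,
                            cell_ids=list(e.cell_ids))


def _tree_path(adj, src, dst):
    """Unique path between two vertices of a tree (BFS with parents)."""
    n = adj.shape[0]
    parent = {src: None}
    queue = [src]
    while queue:
        v = queue.pop(0)
        if v == dst:
            path = [dst]
            while parent[path[-1]] is not None:
                path.append(parent[path[-1]])
            return path[::-1]
        for w in np.flatnonzero(adj[v]):
            if w not in parent:
                parent[w] = v
                queue.append(int(w))
    return None


def _project_polyline(points, vertices, closed):
    """Arc-length position of each point's nearest location on a polyline."""
    segs = np.diff(vertices, axis=0)
    seg_len = np.linalg.norm(segs, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d = np.full(points.shape[0], np.inf)
    best_t = np.zeros(points.shape[0])
    for i, (a, d, l) in enumerate(zip(vertices[:-1], segs, seg_len)):
        if l == 0:
            continue
        u = np.clip((points - a) @ d / (l * l), 0.0, 1.0)
        proj = a + u[:, None] * d
        dd = np.linalg.norm(points - proj, axis=1)
        upd = dd < best_d
        best_d[upd] = dd[upd]
        best_t[upd] = cum[i] + u[upd] * l
    return best_t


# ---------------------------------------------------------------------------
# Cyclical pseudotime
# ---------------------------------------------------------------------------

def select_circular_components(e: EmbeddingResult, max_dc: int = 5,
                               override=None):
    """Pick the diffusion-component pair tracing the most circular loop.

    Circularity of a pair = 1 - (SD of radius / mean radius) about the
    coordinate-wise median.  Returns ``(pair, score)``; a user override is
    honored verbatim (with its computed score).  Scores above
    ``CONFIDENT_CIRCULARITY`` (0.7) are considered confident.
    """
    if e.coordinates.shape[1] < max_dc:
        raise ValueError(f"embedding has < {max_dc} components")

    def score(i, j):
        xy = e.coordinates[:, [i, j]]
        center = np.median(xy, axis=0)
        r = np.linalg.norm(xy - center, axis=1)
        if r.mean() == 0:
            return -np.inf
        return 1.0 - r.std() / r.mean()

    if override is not None:
        i, j = override
        return (i, j), float(score(i, j))
    best_pair, best = None, -np.inf
    for i in range(max_dc):
        for j in range(i + 1, max_dc):
            s = score(i, j)
            if s > best:
                best_pair, best = (i, j), s
    if best <= 0:
        raise ValueError("no circular structure detected (all scores <= 0)")
    return best_pair, float(best)


def fit_cyclical_pseudotime(e: EmbeddingResult, clusters, pair,
                            n_iter: int = 10, span: float = 0.2,
                            n_grid: int = 512,
                            n_grid_final: int = 4096) -> CyclicalPseudotime:
    """Closed principal curve through the cluster ring; phase per cell.

    Cluster centroids in the chosen 2D plane are ordered by angle about
    their barycenter to form the ring; initial phases come from the same
    angles; then ``n_iter`` rounds of periodic local-linear smoothing of
    each coordinate against phase (data replicated at phase +/- 1) followed
    by re-projection onto the smoothed closed polyline, with arc length
    renormalized to [0, 1).  The phase origin is the centroid of the
    lowest-numbered cluster and the orientation makes cluster labels
    increase around the ring where possible.
    """
    clusters = np.asarray(clusters)
    uniq = sorted(pd.unique(clusters), key=str)
    if len(uniq) < 3:
        raise ValueError("need >= 3 clusters for a ring")
    xy = e.coordinates[:, list(pair)]
    centroids = np.array([xy[clusters == k].mean(axis=0) for k in uniq])
    if np.min(pdist(centroids)) < 1e-12:
        raise ValueError("collapsed ring: coincident cluster centroids")
    bary = centroids.mean(axis=0)
    phase = (np.arctan2(xy[:, 1] - bary[1], xy[:, 0] - bary[0])
             / (2 * np.pi)) % 1.0
    curve = None
    for it in range(n_iter):
        # coarse grid during iterations; a fine grid for the last pass keeps
        # the chord-vs-arc discretization error of the phases negligible
        g = n_grid_final if it == n_iter - 1 else n_grid
        grid = np.arange(g) / g
        curve = np.column_stack([
            _periodic_loess(phase, xy[:, 0], grid, span),
            _periodic_loess(phase, xy[:, 1], grid, span),
        ])
        # local regression evaluated on a fine grid ripples at the data
        # sampling frequency; a circular moving average two data-spacings
        # wide removes it without touching the loop geometry
        curve = _circular_smooth(curve, width=2 * g // max(len(phase), 1) + 1)
        closed = np.vstack([curve, curve[:1]])
        arc = _project_polyline(xy, closed, closed=True)
        total = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        phase = (arc / total) % 1.0 if total > 0 else phase

    # conventions: origin at the lowest-numbered cluster's centroid phase,
    # orientation so labels increase around the ring where possible
    closed = np.vstack([curve, curve[:1]])
    total = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
    cent_phase = _project_polyline(centroids, closed, closed=True) / total
    origin = cent_phase[0]
    forward = np.argsort((cent_phase - origin) % 1.0)
    seq_fwd = [uniq[i] for i in forward]
    ring_seq = seq_fwd
    # count label-order agreements in each direction
    fwd_good = _monotone_agreement(seq_fwd)
    rev_good = _monotone_agreement([seq_fwd[0]] + seq_fwd[1:][::-1])
    reflected = rev_good > fwd_good
    phase = (phase - origin) % 1.0
    if reflected:
        phase = (-phase) % 1.0
        ring_seq = [ring_seq[0]] + ring_seq[1:][::-1]
    curve_out = np.vstack([curve, curve[:1]])
    convention = {"origin_cluster": uniq[0], "reflected": bool(reflected),
                  "pair": tuple(pair)}
    return CyclicalPseudotime(phase=phase, pair=tuple(pair), ring=ring_seq,
                              curve=curve_out, convention=convention,
                              cell_ids=list(e.cell_ids))


def _circular_smooth(curve, width):
    """Circular moving average of polyline vertices (width forced odd)."""
    width = max(int(width) | 1, 1)
    if width <= 1:
        return curve
    kernel = np.ones(width) / width
    half = width // 2
    out = np.empty_like(curve)
    for c in range(curve.shape[1]):
        padded = np.concatenate([curve[-half:, c], curve[:, c],
                                 curve[:half, c]])
        out[:, c] = np.convolve(padded, kernel, mode="valid")
    return out


def _monotone_agreement(seq):
    vals = [str(s) for s in seq]
    return sum(1 for a, b in zip(vals, vals[1:]) if a <= b)


def _periodic_loess(x, y, grid, span):
    """Local-linear regression of y on circular x evaluated on grid.

    The data are replicated at x - 1 and x + 1 so windows wrap seamlessly;
    tricube weights over the ``span`` nearest fraction of points.
    """
    x3 = np.concatenate([x - 1.0, x, x + 1.0])
    y3 = np.tile(np.asarray(y, dtype=float), 3)
    return _loess(x3, y3, grid, span_n=max(int(np.ceil(span * len(x))), 4))


def _loess(x, y, grid, span_n):
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(len(grid))
    for i, g in enumerate(grid):
        # span_n nearest points by |x - g|
        pos = np.searchsorted(xs, g)
        lo = max(pos - span_n, 0)
        hi = min(pos + span_n, len(xs))
        xi, yi = xs[lo:hi], ys[lo:hi]
        d = np.abs(xi - g)
        keep = np.argsort(d)[:span_n]
        xi, yi, d = xi[keep], yi[keep], d[keep]
        dmax = d.max()
        if dmax == 0:
            out[i] = yi.mean()
            continue
        w = (1 - (d / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        # weighted linear fit
        sw = w.sum()
        xm = (w * xi).sum() / sw
        ym = (w * yi).sum() / sw
        sxx = (w * (xi - xm) ** 2).sum()
        if sxx < 1e-12:
            out[i] = ym
        else:
            slope = (w * (xi - xm) * (yi - ym)).sum() / sxx
            out[i] = ym + slope * (g - xm)
    return out


# ---------------------------------------------------------------------------
# Gene dynamics
# ---------------------------------------------------------------------------

def fit_gene_dynamics(m: ExpressionMatrix, pt, genes, span: float = 0.3,
                      n_grid: int = 100) -> GeneDynamics:
    """LOESS-style fits of scaled expression against pseudotime.

    Expression is z-scored across cells with defined pseudotime; cyclical
    fits replicate the data at phase +/- 1 so the curve is periodic
    (fit(0) == fit(1-)).  Amplitude is max - min of the fit; peak phase the
    argmax grid point.
    """
    if m.lognorm is None:
        raise ValueError("run normalize_log first")
    missing = [g for g in genes if g not in set(m.gene_ids)]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    cyclical = isinstance(pt, CyclicalPseudotime)
    times = pt.phase if cyclical else pt.t
    defined = np.isfinite(times)
    if defined.sum() < 30:
        raise ValueError("need >= 30 cells with defined pseudotime")
    t = np.asarray(times, dtype=float)[defined]
    idx = m.gene_index(genes)
    expr = m.lognorm[np.ix_(defined, idx)]
    sd = expr.std(axis=0, ddof=0)
    mu = expr.mean(axis=0)
    z = np.where(sd > 0, (expr - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    if cyclical:
        grid = np.arange(n_grid) / n_grid
    else:
        grid = np.linspace(t.min(), t.max(), n_grid)
    curves = np.empty((len(genes), n_grid))
    span_n = max(int(np.ceil(span * len(t))), 4)
    for j in range(len(genes)):
        if sd[j] == 0:
            curves[j] = 0.0
        elif cyclical:
            curves[j] = _periodic_loess(t, z[:, j], grid, span)
        else:
            curves[j] = _loess(t, z[:, j], grid, span_n=span_n)
    amp = curves.max(axis=1) - curves.min(axis=1)
    peak = grid[np.argmax(curves, axis=1)]
    return GeneDynamics(genes=list(genes), grid=grid, curves=curves,
                        amplitude=amp, peak_phase=peak, cyclical=cyclical)


def cluster_gene_waves(d: GeneDynamics, k="auto"):
    """Cluster fitted gene curves into expression waves.

    Distance = 1 - Pearson correlation between fitted curves;
    average-linkage hierarchical clustering; when ``k="auto"`` the cut with
    the best mean silhouette over k in 2..6 is used.  Labels (1..k) are
    ordered by mean peak phase and stored on the input ``GeneDynamics``.
    """
    active = d.amplitude > 0
    if active.sum() < 2:
        raise ValueError("need >= 2 genes with positive amplitude")
    curves = d.curves[active]
    c = np.corrcoef(curves)
    dist = np.clip(1.0 - c, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")
    n = curves.shape[0]
    if k == "auto":
        best_k, best_s = 2, -np.inf
        for kk in range(2, min(6, n - 1) + 1):
            lab = fcluster(link, kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(dist, lab, metric="precomputed")
            if s > best_s:
                best_k, best_s = kk, s
        k = best_k
    labels = fcluster(link, int(k), criterion="maxclust")
    # order labels by circular mean peak phase
    means = {}
    peaks = d.peak_phase[active]
    for lab in np.unique(labels):
        pk = peaks[labels == lab]
        if d.cyclical:
            ang = 2 * np.pi * pk
            means[lab] = (np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
                          / (2 * np.pi)) % 1.0
        else:
            means[lab] = pk.mean()
    remap = {old: new + 1
             for new, old in enumerate(sorted(means, key=means.get))}
    out = np.zeros(len(d.genes), dtype=int)  # 0 = flat gene, unclustered
    out[active] = [remap[l] for l in labels]
    d.wave_cluster = out
    return out


def anchor_dynamics(d: GeneDynamics, anchor, top_k: int = 50) -> pd.DataFrame:
    """Genes whose fitted dynamics track the anchor gene's.

    Ranked by Pearson correlation of fitted curves with the anchor curve
    (positive association only); the anchor is excluded from its own list.
    """
    if anchor not in d.genes:
        raise ValueError(f"anchor {anchor!r} not among fitted genes")
    ai = d.genes.index(anchor)
    if d.amplitude[ai] == 0:
        raise ValueError(f"anchor {anchor!r} has a flat fit")
    ref = d.curves[ai]
    rows = []
    for j, g in enumerate(d.genes):
        if j == ai:
            continue
        cj = d.curves[j]
        if cj.std() == 0:
            continue
        rows.append({"gene": g,
                     "correlation": float(np.corrcoef(ref, cj)[0, 1])})
    out = (pd.DataFrame(rows)
           .sort_values(["correlation", "gene"], ascending=[False, True])
           .reset_index(drop=True))
    return out.head(top_k)
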