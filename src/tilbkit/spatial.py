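"""Delaunay neighborhood analysis of segmented cell maps.

Cells that share a Delaunay edge are "neighbors"; for every ordered pair of
cell types (A, B) each undirected edge contributes its two ordered
endpoint pairs, and the association between being-an-A and
having-a-B-neighbor is summarized as a 2x2 odds ratio (Haldane-corrected
when a cell of the table is zero).  Significance comes from shuffling type
labels over the fixed graph.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from ._stats import bh_adjust


@dataclasses.dataclass
class SpatialCellMap:
    table: pd.DataFrame  # cell_id, x, y, cell_type

    def __post_init__(self):
        required = {"cell_id", "x", "y", "cell_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"spatial table missing columns: {sorted(missing)}")
        xy = self.table[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite coordinates")
        if len(self.table) < 3:
            raise ValueError("need >= 3 cells for triangulation")

    @property
    def xy(self):
        return self.table[["x", "y"]].to_numpy(dtype=float)

    @property
    def types(self):
        return self.table["cell_type"].to_numpy(dtype=object)


def build_delaunay(cell_map: SpatialCellMap, max_edge=None):
    """Delaunay edges of the cell positions, optionally pruned by length.

    Returns a sorted array of undirected (i, j) index pairs, i < j.
    Degenerate inputs (all collinear, duplicate points) raise with a
    suggestion to jitter.
    """
    xy = cell_map.xy
    if len(np.unique(xy, axis=0)) < len(xy):
        raise ValueError("duplicate points; add a small jitter epsilon")
    try:
        tri = Delaunay(xy)
    except QhullError as err:
        raise ValueError(
            "degenerate point set (collinear?); add a small jitter epsilon"
        ) from err
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((min(i, j), max(i, j)))
    edges = np.array(sorted(edges), dtype=int).reshape(-1, 2)
    if max_edge is not None:
        lengths = np.linalg.norm(xy[edges[:, 0]] - xy[edges[:, 1]], axis=1)
        edges = edges[lengths <= max_edge]
    return edges


def neighborhood_odds(cell_map: SpatialCellMap, edges) -> pd.DataFrame:
    """Edge-level interaction odds ratio per ordered cell-type pair.

    Each undirected edge contributes both ordered endpoint pairs.  For the
    pair (A, B): n11 counts ordered pairs (first A, second B), n10 (first A,
    second not B), n01 (first not A, second B), n00 the rest; OR =
    n11*n00 / (n10*n01), with +0.5 Haldane correction (and a degeneracy
    flag) when any count is zero.

    Returns a DataFrame (type_a, type_b, n11, n10, n01, n00, odds_ratio,
    degenerate).
    """
    types = cell_map.types
    names = sorted(set(types))
    if len(names) < 2:
        raise ValueError("need >= 2 cell types")
    edges = np.asarray(edges, dtype=int)
    if len(edges) == 0:
        raise ValueError("empty edge list")
    first = np.concatenate([types[edges[:, 0]], types[edges[:, 1]]])
    second = np.concatenate([types[edges[:, 1]], types[edges[:, 0]]])
    return _odds_from_pairs(first, second, names)


def _odds_from_pairs(first, second, names):
    rows = []
    total = len(first)
    for a in names:
        fa = first == a
        for b in names:
            sb = second == b
            n11 = int(np.sum(fa & sb))
            n10 = int(np.sum(fa & ~sb))
            n01 = int(np.sum(~fa & sb))
            n00 = total - n11 - n10 - n01
            degenerate = min(n11, n10, n01, n00) == 0
            if degenerate:
                c11, c10, c01, c00 = (n11 + 0.5, n10 + 0.5,
                                      n01 + 0.5, n00 + 0.5)
            else:
                c11, c10, c01, c00 = n11, n10, n01, n00
            rows.append({
                "type_a": a, "type_b": b,
                "n11": n11, "n10": n10, "n01": n01, "n00": n00,
                "odds_ratio": (c11 * c00) / (c10 * c01),
                "degenerate": degenerate,
            })
    return pd.DataFrame(rows)


def _log_odds_matrix(codes, edges, k):
    """log odds ratio per ordered type pair, Haldane-corrected; (k, k)."""
    first = np.concatenate([codes[edges[:, 0]], codes[edges[:, 1]]])
    second = np.concatenate([codes[edges[:, 1]], codes[edges[:, 0]]])
    c = np.bincount(first * k + second, minlength=k * k).reshape(k, k).astype(float)
    total = c.sum()
    n11 = c
    n10 = c.sum(axis=1, keepdims=True) - c
    n01 = c.sum(axis=0, keepdims=True) - c
    n00 = total - n11 - n10 - n01
    stacked = np.stack([n11, n10, n01, n00])
    degen = stacked.min(axis=0) == 0
    corr = np.where(degen[None, :, :], stacked + 0.5, stacked)
    return np.log(corr[0] * corr[3] / (corr[1] * corr[2]))


def permutation_significance(cell_map: SpatialCellMap, edges,
                             n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Permutation p-values for the neighborhood odds ratios.

    Type labels are shuffled over the fixed positions/graph ``n_perm``
    times; the two-sided empirical p for each ordered pair is
    ``(1 + #{|log OR_perm| >= |log OR_obs|}) / (n_perm + 1)``, BH-corrected
    across pairs.
    """
    if n_perm < 99:
        raise ValueError("need n_perm >= 99")
    obs = neighborhood_odds(cell_map, edges)
    types = cell_map.types
    names = sorted(set(types))
    k = len(names)
    codes = np.array([names.index(t) for t in types])
    edges = np.asarray(edges, dtype=int)
    rng = np.random.default_rng(seed)
    log_obs = np.log(obs["odds_ratio"].to_numpy())
    exceed = np.zeros(len(obs), dtype=int)
    for _ in range(n_perm):
        shuffled = rng.permutation(codes)
        log_perm = _log_odds_matrix(shuffled, edges, k).ravel()
        exceed += np.abs(log_perm) >= np.abs(log_obs) - 1e-12
    out = obs.copy()
    out["p"] = (1 + exceed) / (n_perm + 1)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["n_permutations"] = n_perm
    return out
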