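import itertools

import numpy as np
import pandas as pd
import pytest

from tilbkit.io_config import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """4 cells x 5 genes with deterministic small counts."""
    counts = np.array([
        [10, 0, 3, 1, 0],
        [2, 5, 0, 0, 1],
        [0, 1, 8, 2, 4],
        [7, 3, 2, 9, 0],
    ])
    return ExpressionMatrix([f"c{i}" for i in range(4)],
                            [f"g{j}" for j in range(5)], counts)


def lognorm_matrix(values, cell_prefix="c", gene_prefix="g"):
    """Build an ExpressionMatrix whose lognorm layer is ``values`` directly
    (counts zero); used when a test needs full control of the layer."""
    values = np.asarray(values, dtype=float)
    m = ExpressionMatrix(
        [f"{cell_prefix}{i}" for i in range(values.shape[0])],
        [f"{gene_prefix}{j}" for j in range(values.shape[1])],
        np.zeros(values.shape, dtype=int),
    )
    m.lognorm = values
    return m


def enumerate_ranksum_p(ranks, m, observed, alternative):
    """Exhaustive rank-placement enumeration oracle for the subset rank-sum."""
    ranks = list(ranks)
    n = len(ranks)
    mu = m * (n + 1) / 2.0
    hits = total = 0
    for combo in itertools.combinations(ranks, m):
        s = sum(combo)
        total += 1
        if alternative == "greater":
            hits += s >= observed - 1e-9
        else:
            hits += abs(s - mu) >= abs(observed - mu) - 1e-9
    return hits / total


def brute_delaunay_edges(xy):
    """O(n^4) empty-circumcircle Delaunay oracle."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    edges = set()
    for tri in itertools.combinations(range(n), 3):
        a, b, c = xy[list(tri)]
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1])
                 + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            continue
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1])
              + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0])
              + (c @ c) * (b[0] - a[0])) / d
        center = np.array([ux, uy])
        radius = np.linalg.norm(a - center)
        empty = all(
            np.linalg.norm(xy[k] - center) >= radius - 1e-9
            for k in range(n) if k not in tri
        )
        if empty:
            for e in itertools.combinations(sorted(tri), 2):
                edges.add(e)
    return edges
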