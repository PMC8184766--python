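"""Readers, writers, and run configuration for the TIL-B analysis pipeline.

All matrices are cell x gene internally.  Files written by this module state
that orientation in their headers.  Gene and cell ids are case-sensitive exact
strings; no symbol aliasing is performed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("tilbkit")

DEFAULT_GROUPS = (
    "HD_PBMC",
    "tonsil",
    "HPVneg_PBL",
    "HPVneg_TIL",
    "HPVpos_PBL",
    "HPVpos_TIL",
)


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionMatrix:
    """Cells x genes UMI counts with an optional log-normalized layer.

    ``counts`` holds nonnegative integers; ``lognorm`` (same shape) is filled
    by :func:`tilbkit.preprocess.normalize_log` and is ``None`` until then.
    """

    cell_ids: list
    gene_ids: list
    counts: np.ndarray
    lognorm: Optional[np.ndarray] = None

    def __post_init__(self):
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.counts = np.asarray(self.counts)
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise LoadError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        _check_counts(self.counts, self.cell_ids, self.gene_ids)
        self.counts = self.counts.astype(np.int64)
        if self.lognorm is not None:
            self.lognorm = np.asarray(self.lognorm, dtype=float)
            if self.lognorm.shape != self.counts.shape:
                raise LoadError("lognorm shape differs from counts shape")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, genes) -> np.ndarray:
        """Integer positions of ``genes``; raises on absent ids."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclasses.dataclass
class CellMeta:
    """Per-cell annotations aligned with an :class:`ExpressionMatrix`."""

    table: pd.DataFrame  # columns: cell_id, sample_id, group[, cluster, truth_label]

    def __post_init__(self):
        required = {"cell_id", "sample_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise LoadError(f"cell metadata missing columns: {sorted(missing)}")
        if self.table["cell_id"].duplicated().any():
            dupes = self.table.loc[self.table["cell_id"].duplicated(), "cell_id"]
            raise LoadError(f"duplicate cell ids in metadata: {list(dupes)[:5]}")

    def validate_against(self, m: ExpressionMatrix,
                         vocabulary=DEFAULT_GROUPS) -> None:
        if set(self.table["cell_id"]) != set(m.cell_ids):
            raise LoadError("metadata cell ids do not match expression matrix")
        bad = set(self.table["group"]) - set(vocabulary)
        if bad:
            raise LoadError(f"groups outside declared vocabulary: {sorted(bad)}")


class GeneSetCollection(dict):
    """Mapping of set name -> ordered list of gene ids."""

    def __init__(self, sets):
        super().__init__()
        for name, genes in dict(sets).items():
            if not genes:
                raise LoadError(f"gene set {name!r} is empty")
            self[name] = list(dict.fromkeys(str(g) for g in genes))


@dataclasses.dataclass
class RunConfig:
    """Seed + stage parameters + output directory for one pipeline run."""

    seed: int = 0
    out_dir: str = "."
    params: dict = dataclasses.field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


# ---------------------------------------------------------------------------
# Validation helpers
# ---------------------------------------------------------------------------

def _check_unique(ids, what):
    seen, dupes = set(), []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise LoadError(f"duplicate {what} ids: {sorted(set(dupes))[:10]}")


def _check_counts(counts, cell_ids, gene_ids):
    if counts.size == 0:
        return
    arr = np.asarray(counts, dtype=float)
    bad = ~np.isfinite(arr) | (arr < 0) | (arr != np.round(arr))
    if bad.any():
        c, g = map(int, np.argwhere(bad)[0])
        raise LoadError(
            f"counts must be nonnegative integers; offending value "
            f"{arr[c, g]!r} at cell {cell_ids[c]!r}, gene {gene_ids[g]!r}"
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_counts(path, format: str = "mtx_triplet") -> ExpressionMatrix:
    """Load a UMI count matrix.

    ``mtx_triplet`` expects a directory holding ``matrix.mtx`` plus
    ``barcodes.tsv`` and ``features.tsv`` (CellRanger dialect, stored
    gene x cell and transposed here to cell x gene).  ``csv_dense`` expects a
    table whose first column is the cell id and whose header names the genes.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mat = scipy.io.mmread(path / "matrix.mtx")
        barcodes = _read_id_column(path / "barcodes.tsv")
        features = _read_id_column(path / "features.tsv")
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        # CellRanger stores genes as rows
        if dense.shape != (len(features), len(barcodes)):
            raise LoadError(
                f"matrix is {dense.shape} but there are {len(features)} "
                f"features and {len(barcodes)} barcodes"
            )
        return ExpressionMatrix(barcodes, features, dense.T)
    if format == "csv_dense":
        df = pd.read_csv(path, index_col=0)
        return ExpressionMatrix(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(),
        )
    raise LoadError(f"unknown counts format {format!r}")


def _read_id_column(path):
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: per line name, description, members (tab-separated).

    The description is discarded; duplicate members within one set are
    de-duplicated preserving first occurrence.
    """
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(
                    f"GMT line {lineno} has {len(fields)} fields; "
                    "expected name, description, members..."
                )
            name = fields[0]
            if name in sets:
                raise LoadError(f"duplicate gene set name {name!r} at line {lineno}")
            sets[name] = list(dict.fromkeys(fields[2:]))
    return GeneSetCollection(sets)


def read_cell_meta(path) -> CellMeta:
    return CellMeta(pd.read_csv(path, dtype={"cell_id": str, "sample_id": str}))


def read_spatial_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str})
    required = {"cell_id", "x", "y", "cell_type"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"spatial table missing columns: {sorted(missing)}")
    return df


def read_survival_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"survival table missing columns: {sorted(missing)}")
    if (df["time"] <= 0).any():
        bad = df.loc[df["time"] <= 0, "patient_id"].tolist()
        raise LoadError(f"nonpositive survival times for patients {bad[:5]}")
    if not df["event"].isin([0, 1]).all():
        raise LoadError("event indicator must be 0/1")
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_counts_csv(m: ExpressionMatrix, path) -> None:
    """Write counts as dense CSV, rows = cells, columns = genes."""
    pd.DataFrame(m.counts, index=pd.Index(m.cell_ids, name="cell_id"),
                 columns=m.gene_ids).to_csv(path)


def write_gene_sets(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na"] + list(genes)) + "\n")


def write_manifest(path, config: RunConfig, inputs=None, outputs=None) -> None:
    import tilbkit
    manifest = {
        "inputs": inputs or {},
        "outputs": outputs or {},
        "parameters": config.params,
        "seed": config.seed,
        "versions": {"tilbkit": tilbkit.__version__, "numpy": np.__version__},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run manifest written to %s (seed=%d)", path, config.seed)
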