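"""Two-step semi-supervised immune-lineage identification.

Step one derives a ~20-gene "core program" per lineage from a labeled
reference by rank-sum differential expression.  Step two scores every cell
of the target dataset for enrichment of each program — the cell's gene-wise
log-fold-changes against the dataset mean are ranked and the in-program
ranks tested by a one-sided Wilcoxon rank-sum — and assigns the
lowest-p program.  Clusters then adopt the modal per-cell call, and the
result is validated against ground truth with a confusion table.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from . import _stats
from .io_config import ExpressionMatrix
from .preprocess import normalize_log


@dataclasses.dataclass
class CoreProgram:
    """A named lineage gene set (top differential markers)."""

    lineage: str
    genes: list

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in program {self.lineage!r}")
        if len(self.genes) < 2:
            raise ValueError(f"program {self.lineage!r} needs >= 2 genes")


MIN_REF_CELLS = 10


def derive_core_programs(ref: ExpressionMatrix, labels, top_n: int = 20):
    """Derive core lineage programs from a labeled reference matrix.

    Per lineage, every gene's lognorm is tested lineage-vs-rest by a
    one-sided Wilcoxon rank-sum; genes with positive log-fold-change are
    ranked by p ascending (log-fold-change descending, then gene id, as
    tie-breaks) and the top ``top_n`` kept.  Warns when no gene survives a
    within-lineage BH correction at 0.05 (exchangeable lineages) or when
    fewer than ``top_n`` genes are eligible.
    """
    if ref.lognorm is None:
        raise ValueError("reference matrix needs lognorm; run normalize_log")
    labels = np.asarray(labels)
    lineages = sorted(set(labels))
    if len(lineages) < 2:
        raise ValueError("need >= 2 lineages")
    small = [l for l in lineages if (labels == l).sum() < MIN_REF_CELLS]
    if small:
        raise ValueError(f"lineages with < {MIN_REF_CELLS} cells: {small}")

    programs = []
    for lineage in lineages:
        mask = labels == lineage
        x, y = ref.lognorm[mask], ref.lognorm[~mask]
        lfc = x.mean(axis=0) - y.mean(axis=0)
        res = mannwhitneyu(x, y, alternative="greater", axis=0,
                           method="asymptotic")
        pvals = np.asarray(res.pvalue)
        if not np.any(_stats.bh_adjust(pvals) < 0.05):
            warnings.warn(
                f"no gene significant after BH for lineage {lineage!r}; "
                "lineages may be exchangeable"
            )
        eligible = np.flatnonzero(lfc > 0)
        if len(eligible) < top_n:
            warnings.warn(
                f"only {len(eligible)} eligible genes for lineage "
                f"{lineage!r}; program will be shorter than {top_n}"
            )
        order = sorted(eligible,
                       key=lambda j: (pvals[j], -lfc[j], ref.gene_ids[j]))
        genes = [ref.gene_ids[j] for j in order[:top_n]]
        programs.append(CoreProgram(lineage=str(lineage), genes=genes))
    return programs


EXACT_MAX_SET = 10
EXACT_MAX_GENES = 25


def score_cells(m: ExpressionMatrix, programs, pseudo: float = 0.01,
                method: str = "auto") -> pd.DataFrame:
    """Score every cell for enrichment of each core program.

    Per cell the log-fold-change ``lfc_g = lognorm[c, g] - mean_c'
    lognorm[c', g]`` is computed against the dataset mean; per program a
    one-sided (greater) Wilcoxon rank-sum compares in-program versus
    out-of-program fold-changes with tie and continuity corrections,
    switching to exact enumeration for tiny instances (set <= 10 genes,
    matrix <= 25 genes).  ``pseudo`` is the pseudocount used to build a
    lognorm layer on the fly when the matrix arrives with raw counts only.

    Returns a DataFrame with one row per cell: ``stat_<program>``
    (standardized rank-sum), ``p_<program>``, and ``assigned_lineage``
    (smallest p; ties broken by larger statistic, then program name).
    """
    if m.lognorm is None:
        m = normalize_log(m, pseudocount=pseudo)
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    present_idx = {}
    for prog in programs:
        present = [g for g in prog.genes if g in set(m.gene_ids)]
        dropped = set(prog.genes) - set(present)
        if dropped:
            warnings.warn(
                f"program {prog.lineage!r}: dropping absent genes "
                f"{sorted(dropped)}"
            )
        if len(present) < 2:
            raise ValueError(
                f"program {prog.lineage!r} has < 2 members present"
            )
        present_idx[prog.lineage] = m.gene_index(present)

    lfc = m.lognorm - m.lognorm.mean(axis=0, keepdims=True)
    ranks = rankdata(lfc, axis=1)
    n_genes = m.n_genes
    ties_per_cell = np.array([_stats.tie_term(lfc[c]) for c in range(m.n_cells)])
    out = {"cell_id": list(m.cell_ids)}
    stats_cols, p_cols = {}, {}
    for lineage, idx in present_idx.items():
        m_set = len(idx)
        rsum = ranks[:, idx].sum(axis=1)
        use_exact = (method == "exact") or (
            method == "auto" and m_set <= EXACT_MAX_SET
            and n_genes <= EXACT_MAX_GENES
        )
        mu = m_set * (n_genes + 1) / 2.0
        var = (m_set * (n_genes - m_set) / 12.0
               * ((n_genes + 1) - ties_per_cell / (n_genes * (n_genes - 1))))
        zstat = np.where(var > 0, (rsum - mu) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
        if use_exact:
            pvals = np.array([
                _stats.ranksum_exact_p(ranks[c], m_set, rsum[c],
                                       alternative="greater")
                for c in range(m.n_cells)
            ])
        else:
            pvals = np.array([
                _stats.ranksum_normal_p(rsum[c], m_set, n_genes,
                                        ties_per_cell[c], alternative="greater")
                for c in range(m.n_cells)
            ])
        stats_cols[lineage] = zstat
        p_cols[lineage] = pvals

    names = sorted(present_idx)
    p_mat = np.column_stack([p_cols[l] for l in names])
    z_mat = np.column_stack([stats_cols[l] for l in names])
    assigned = []
    for c in range(m.n_cells):
        best = sorted(range(len(names)),
                      key=lambda j: (p_mat[c, j], -z_mat[c, j], names[j]))[0]
        assigned.append(names[best])
    for l in names:
        out[f"stat_{l}"] = stats_cols[l]
        out[f"p_{l}"] = p_cols[l]
    out["assigned_lineage"] = assigned
    return pd.DataFrame(out)


def label_clusters(scores: pd.DataFrame, clusters):
    """Identify clusters by the modal per-cell assignment.

    Returns ``(cluster_table, final_labels)``: a per-cluster DataFrame with
    the voted lineage and a tie flag, and a per-cell Series of inherited
    labels aligned with ``scores``.  Ties break lexicographically and are
    flagged.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(scores):
        raise ValueError("clusters and scores length mismatch")
    rows = []
    final = pd.Series(index=scores.index, dtype=object)
    for k in sorted(pd.unique(clusters), key=lambda v: (str(v))):
        mask = clusters == k
        if not mask.any():
            raise ValueError(f"empty cluster {k!r}")
        counts = scores.loc[mask, "assigned_lineage"].value_counts()
        top = counts.max()
        winners = sorted(counts[counts == top].index)
        rows.append({"cluster": k, "lineage": winners[0],
                     "n_cells": int(mask.sum()), "tie": len(winners) > 1})
        final[mask] = winners[0]
    return pd.DataFrame(rows), final


def evaluate_confusion(final, truth):
    """Confusion table (rows = truth, columns = predicted) with accuracy
    and per-class sensitivity."""
    final = np.asarray(final, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(final) != len(truth):
        raise ValueError("label vectors differ in length")
    classes = sorted(set(truth) | set(final))
    table = pd.crosstab(
        pd.Categorical(truth, categories=classes),
        pd.Categorical(final, categories=classes),
        rownames=["truth"], colnames=["predicted"], dropna=False,
    )
    diag = np.diag(table.to_numpy())
    accuracy = diag.sum() / len(truth)
    row_sums = table.sum(axis=1).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row_sums > 0, diag / row_sums, np.nan)
    sensitivity = pd.Series(sens, index=classes, name="sensitivity")
    return table, float(accuracy), sensitivity
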