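"""Cluster markers, variance-inflation-corrected gene-set tests, and
cluster-by-group enrichment ratios.

The gene-set test ranks all genes by their cluster-vs-rest log-fold-change
and asks whether a set's ranks are shifted in a concerted way.  Because
member genes of a real gene set are co-expressed, the naive rank-sum
variance understates the null spread; the test inflates it by
``VIF = 1 + (m - 1) * rho_bar`` where ``rho_bar`` is the mean pairwise
correlation of the member genes across the tested cluster's cells
(floored at zero).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, mannwhitneyu, norm, rankdata

from . import _stats
from .io_config import ExpressionMatrix, GeneSetCollection

EXACT_MAX_CELLS = 25


@dataclasses.dataclass
class EnrichmentRatioTable:
    """Observed/expected cluster-by-group cell frequencies with tests."""

    ratios: pd.DataFrame     # cluster, group, observed, expected, ratio
    anova: pd.DataFrame      # cluster, p
    contrasts: pd.DataFrame  # cluster, group_a, group_b, p


def cluster_markers(m: ExpressionMatrix, clusters) -> pd.DataFrame:
    """Per-cluster differential expression versus all other cells.

    Returns a long DataFrame (gene, cluster, logfc, p, p_adj): logfc is the
    mean lognorm difference, p a two-sided Wilcoxon rank-sum (exact by
    rank-placement enumeration when the dataset has <= 25 cells), p_adj the
    BH adjustment within each cluster.
    """
    if m.lognorm is None:
        raise ValueError("run normalize_log first")
    clusters = np.asarray(clusters)
    uniq = sorted(pd.unique(clusters), key=str)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    small = [k for k in uniq if (clusters == k).sum() < 3]
    if small:
        raise ValueError(f"clusters with < 3 cells: {small}")
    frames = []
    exact = m.n_cells <= EXACT_MAX_CELLS
    for k in uniq:
        mask = clusters == k
        x, y = m.lognorm[mask], m.lognorm[~mask]
        logfc = x.mean(axis=0) - y.mean(axis=0)
        if exact:
            pvals = np.empty(m.n_genes)
            m_in = int(mask.sum())
            for j in range(m.n_genes):
                col = m.lognorm[:, j]
                r = _stats.midranks(col)
                pvals[j] = _stats.ranksum_exact_p(
                    r, m_in, r[mask].sum(), alternative="two-sided")
        else:
            res = mannwhitneyu(x, y, alternative="two-sided", axis=0,
                               method="asymptotic")
            pvals = np.asarray(res.pvalue)
        frames.append(pd.DataFrame({
            "gene": m.gene_ids,
            "cluster": k,
            "logfc": logfc,
            "p": pvals,
            "p_adj": _stats.bh_adjust(pvals),
        }))
    return pd.concat(frames, ignore_index=True)


def gsea_vif_test(m: ExpressionMatrix, markers: pd.DataFrame,
                  sets: GeneSetCollection, clusters) -> pd.DataFrame:
    """Variance-inflation-corrected rank-sum gene-set test per cluster.

    Genes are ranked by their cluster log-fold-change; for a set S of size
    m among N genes the rank-sum U is compared with the null mean
    m(N+1)/2 and variance VIF * m(N-m)(N+1)/12, where VIF = 1+(m-1)*rho_bar
    and rho_bar is the mean pairwise Pearson correlation of the member
    genes' lognorm across the tested cluster's cells, floored at 0.

    Returns a DataFrame (set, cluster, n_genes, stat, vif, z, p, p_adj);
    sets with < 3 present members are skipped with a warning; BH adjustment
    is across all (set, cluster) pairs.
    """
    if m.lognorm is None:
        raise ValueError("run normalize_log first")
    clusters = np.asarray(clusters)
    gene_pos = {g: j for j, g in enumerate(m.gene_ids)}
    rows = []
    for k in sorted(pd.unique(clusters), key=str):
        sub = markers[markers["cluster"] == k]
        sub = sub.set_index("gene")["logfc"]
        genes = list(sub.index)
        ranks = pd.Series(rankdata(sub.to_numpy()), index=genes)
        n_total = len(genes)
        cell_mask = clusters == k
        for name, members in sets.items():
            present = [g for g in members if g in sub.index]
            m_set = len(present)
            if m_set < 3:
                warnings.warn(
                    f"set {name!r} has {m_set} present members in cluster "
                    f"{k!r}; skipped"
                )
                continue
            u = float(ranks[present].sum())
            mu = m_set * (n_total + 1) / 2.0
            var0 = m_set * (n_total - m_set) * (n_total + 1) / 12.0
            expr = m.lognorm[np.ix_(cell_mask, [gene_pos[g] for g in present])]
            rho = _mean_pairwise_corr(expr)
            vif = 1.0 + (m_set - 1) * max(rho, 0.0)
            z = (u - mu) / np.sqrt(vif * var0)
            p = 2.0 * norm.sf(abs(z))
            rows.append({"set": name, "cluster": k, "n_genes": m_set,
                         "stat": u, "vif": vif, "z": z,
                         "p": min(max(p, np.finfo(float).tiny), 1.0)})
    if not rows:
        raise ValueError("no testable (set, cluster) pair")
    out = pd.DataFrame(rows)
    out["p_adj"] = _stats.bh_adjust(out["p"].to_numpy())
    return out


def _mean_pairwise_corr(expr):
    """Mean pairwise Pearson correlation across columns; zero-variance
    columns contribute nothing."""
    sd = expr.std(axis=0, ddof=0)
    keep = sd > 0
    if keep.sum() < 2:
        return 0.0
    c = np.corrcoef(expr[:, keep], rowvar=False)
    iu = np.triu_indices_from(c, k=1)
    vals = c[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else 0.0


def group_cluster_enrichment(meta: pd.DataFrame, contrasts=(),
                             clusters=None) -> EnrichmentRatioTable:
    """Observed/expected patient-normalized cell frequencies per cluster x group.

    ``observed_gk`` = (cells of group g in cluster k) / (patients in g);
    ``expected_gk`` = (total normalized cells of g) / (number of clusters).
    Per cluster a one-way ANOVA compares per-sample frequencies across
    groups; for each declared (group_a, group_b) contrast a two-sided
    rank-sum compares per-sample frequencies (NA when a side has one
    sample).  ``clusters`` may declare the full cluster vocabulary so that
    clusters with zero cells overall still get (zero-observed) rows.
    """
    df = meta.table if hasattr(meta, "table") else meta
    required = {"cell_id", "sample_id", "group", "cluster"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    groups = sorted(df["group"].unique())
    if clusters is None:
        all_clusters = sorted(df["cluster"].unique(), key=str)
    else:
        all_clusters = sorted(set(clusters) | set(df["cluster"].unique()),
                              key=str)
    n_clusters = len(all_clusters)

    rows = []
    for g in groups:
        gdf = df[df["group"] == g]
        n_pat = gdf["sample_id"].nunique()
        total_norm = len(gdf) / n_pat
        expected = total_norm / n_clusters
        counts = gdf["cluster"].value_counts()
        for k in all_clusters:
            obs = counts.get(k, 0) / n_pat
            rows.append({"cluster": k, "group": g, "observed": obs,
                         "expected": expected,
                         "ratio": obs / expected if expected > 0 else np.nan})
    ratios = pd.DataFrame(rows)

    # per-sample frequency of each cluster
    sample_tot = df.groupby("sample_id").size()
    sample_group = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
    freq = (df.groupby(["sample_id", "cluster"]).size()
            .unstack(fill_value=0)
            .reindex(columns=all_clusters, fill_value=0)
            .div(sample_tot, axis=0))

    anova_rows = []
    for k in all_clusters:
        per_group = [freq.loc[sample_group == g, k].to_numpy() for g in groups]
        per_group = [v for v in per_group if len(v) > 0]
        # ANOVA needs between- and within-group degrees of freedom
        if len(per_group) >= 2 and sum(len(v) for v in per_group) > len(per_group):
            with np.errstate(invalid="ignore", divide="ignore"), \
                    warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    p = float(f_oneway(*per_group).pvalue)
                except Exception:
                    p = np.nan
        else:
            p = np.nan
        anova_rows.append({"cluster": k, "p": p})

    contrast_rows = []
    for ga, gb in contrasts:
        for k in all_clusters:
            a = freq.loc[sample_group == ga, k].to_numpy()
            b = freq.loc[sample_group == gb, k].to_numpy()
            if len(a) < 2 or len(b) < 2:
                p = np.nan
            else:
                p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
            contrast_rows.append({"cluster": k, "group_a": ga,
                                  "group_b": gb, "p": p})
    return EnrichmentRatioTable(
        ratios=ratios,
        anova=pd.DataFrame(anova_rows),
        contrasts=pd.DataFrame(contrast_rows,
                               columns=["cluster", "group_a", "group_b", "p"]),
    )
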