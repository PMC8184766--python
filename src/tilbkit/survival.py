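"""Signature derivation, per-sample KS enrichment scoring, optimal-cutpoint
stratification, and Cox / log-rank survival analysis.

The per-patient enrichment score is a signed two-sample Kolmogorov-Smirnov
statistic: genes are ranked by expression within the patient and the
supremum ECDF difference between signature and non-signature genes is
taken, signed by its direction, so high scores mean the signature sits at
the top of the patient's transcriptome.  Patients are then dichotomized at
the score cutpoint maximizing the log-rank statistic (the usual "cutp"
procedure) — which is anti-conservative, so a label-permutation-adjusted p
is co-reported — and compared by Cox proportional hazards regression with
Breslow tie handling.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2, kstwobign, norm


@dataclasses.dataclass
class Signature:
    name: str
    genes: list
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


@dataclasses.dataclass
class SurvivalFit:
    cutpoint: Optional[float]
    n_high: int
    n_low: int
    coef: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float
    logrank_chi2: float
    logrank_p: float
    separation_flag: bool = False
    permutation_p: Optional[float] = None


# ---------------------------------------------------------------------------
# Signature derivation
# ---------------------------------------------------------------------------

def derive_signatures(markers: pd.DataFrame, mode: str, name: str = "signature",
                      target_clusters=None, lfc_threshold: float = 0.5,
                      top_n: int = 200) -> Signature:
    """Build a gene signature from a cluster-marker table.

    ``mode="lineage"``: all genes with logfc > ``lfc_threshold`` for the
    target cluster(s).  ``mode="cluster_top"``: the union of the top
    ``top_n`` genes by logfc for each named cluster, de-duplicated.
    """
    if mode not in ("lineage", "cluster_top"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = markers
    if target_clusters is not None:
        sub = markers[markers["cluster"].isin(list(target_clusters))]
    if sub.empty:
        raise ValueError("no marker rows for the requested clusters")
    if mode == "lineage":
        genes = (sub[sub["logfc"] > lfc_threshold]
                 .sort_values(["logfc", "gene"], ascending=[False, True])
                 ["gene"].drop_duplicates().tolist())
        prov = {"lineage_lfc_threshold": lfc_threshold}
    else:
        genes = []
        for k, grp in sub.groupby("cluster", sort=True):
            top = (grp.sort_values(["logfc", "gene"], ascending=[False, True])
                   .head(top_n)["gene"].tolist())
            genes.extend(top)
        genes = list(dict.fromkeys(genes))
        prov = {"top_n_markers": top_n}
    if not genes:
        raise ValueError(
            "signature came out empty; lower lfc_threshold or check markers"
        )
    return Signature(name=name, genes=genes, provenance=prov)


# ---------------------------------------------------------------------------
# KS enrichment score
# ---------------------------------------------------------------------------

def ks_enrichment_score(expr: pd.DataFrame, sig: Signature) -> pd.DataFrame:
    """Signed KS enrichment score per patient.

    Per patient, genes are ranked by expression descending (ties by gene
    id); D+ is the supremum of (in-set ECDF - out-set ECDF) over rank
    positions and D- the supremum of the reverse; the signed score has
    magnitude max(D+, D-) and the sign of the first extremum of the ECDF
    difference (so swapping the set with its complement flips the sign
    exactly).  The p-value is the asymptotic two-sample KS tail for sizes
    (m, N - m).

    ``expr`` is a patient x gene table; returns a DataFrame
    (patient_id, set, D, p).
    """
    genes = list(expr.columns)
    in_set = np.array([g in set(sig.genes) for g in genes])
    m = int(in_set.sum())
    n_out = len(genes) - m
    if m < 3 or n_out < 3:
        raise ValueError(
            f"need >= 3 signature and >= 3 background genes present "
            f"(got {m} and {n_out})"
        )
    # rank by expression descending, ties broken by gene id
    gene_order = np.array(genes, dtype=object)
    vals = expr.to_numpy(dtype=float)
    rows = []
    for pi, patient in enumerate(expr.index):
        order = np.lexsort((gene_order, -vals[pi]))
        member = in_set[order]
        ecdf_in = np.cumsum(member) / m
        ecdf_out = np.cumsum(~member) / n_out
        diff = ecdf_in - ecdf_out
        # sign taken from the first extremum of the ECDF difference; the
        # difference path negates under set/complement swap, so the signed
        # statistic is exactly antisymmetric even when D+ equals D-
        d = float(diff[np.argmax(np.abs(diff))])
        en = np.sqrt(m * n_out / (m + n_out))
        p = float(min(max(kstwobign.sf(en * abs(d)), np.finfo(float).tiny), 1.0))
        rows.append({"patient_id": str(patient), "set": sig.name,
                     "D": d, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Log-rank machinery (vectorized over candidate cutpoints)
# ---------------------------------------------------------------------------

def logrank_chi2_stat(high, time, event):
    """Two-group log-rank chi-square for a boolean ``high`` split."""
    return _logrank_many(np.asarray(high, bool)[None, :],
                         np.asarray(time, float),
                         np.asarray(event, int))[0]


def _logrank_many(high_matrix, time, event):
    """Log-rank chi-square for many splits at once.

    ``high_matrix`` is (n_splits, n_patients) boolean.  Standard
    observed-minus-expected events in group 1 with hypergeometric variance
    at each distinct event time.
    """
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    hm = high_matrix[:, order].astype(float)
    n = len(time)
    uniq_times, first_idx = np.unique(time, return_index=True)
    # at-risk counts: patients with time >= t
    stats = np.zeros(high_matrix.shape[0])
    var = np.zeros(high_matrix.shape[0])
    # suffix sums of group membership
    suffix = np.cumsum(hm[:, ::-1], axis=1)[:, ::-1]
    ev = event.astype(float)
    ev_h = hm * ev[None, :]
    for t_idx, start in zip(uniq_times, first_idx):
        stop = start
        while stop < n and time[stop] == t_idx:
            stop += 1
        d = ev[start:stop].sum()
        if d == 0:
            continue
        at_risk = n - start
        n1 = suffix[:, start]
        d1 = ev_h[:, start:stop].sum(axis=1)
        e1 = d * n1 / at_risk
        if at_risk > 1:
            v = (d * (n1 / at_risk) * (1 - n1 / at_risk)
                 * (at_risk - d) / (at_risk - 1))
        else:
            v = np.zeros_like(n1)
        stats += d1 - e1
        var += v
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = np.where(var > 0, stats ** 2 / var, 0.0)
    return chi


def optimal_cutpoint(scores, time, event, min_frac: float = 0.1,
                     n_perm: int = 200, seed: int = 0):
    """Score cutpoint maximizing the log-rank chi-square.

    Candidates are midpoints between consecutive sorted unique scores
    leaving at least ``min_frac`` of patients on each side; ties take the
    smaller cutpoint.  Because the maximization inflates the nominal
    log-rank p, a permutation-adjusted p (scores shuffled, optimization
    repeated) is computed when ``n_perm`` > 0.

    Returns a dict with cutpoint, the boolean high-group mask, the nominal
    chi-square/p at the chosen cutpoint, and the permutation-adjusted p.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(scores)
    if n < 10:
        raise ValueError("need >= 10 patients")
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("all scores equal; no cutpoint exists")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n_low = np.searchsorted(np.sort(scores), mids, side="right")
    feasible = (n_low >= min_frac * n) & ((n - n_low) >= min_frac * n)
    mids = mids[feasible]
    if len(mids) == 0:
        raise ValueError("no cutpoint satisfies the min_frac constraint")

    def best_cut(sc):
        hm = sc[None, :] > mids[:, None]
        chi = _logrank_many(hm, time, event)
        i = int(np.argmax(chi))  # argmax takes the first (smaller) tie
        return float(mids[i]), float(chi[i])

    cut, chi_obs = best_cut(scores)
    p_nominal = float(chi2.sf(chi_obs, df=1))
    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            _, chi_p = best_cut(rng.permutation(scores))
            if chi_p >= chi_obs:
                exceed += 1
        p_perm = (1 + exceed) / (n_perm + 1)
    return {
        "cutpoint": cut,
        "high": scores > cut,
        "chi2": chi_obs,
        "p_nominal": p_nominal,
        "p_permutation": p_perm,
    }


# ---------------------------------------------------------------------------
# Cox proportional hazards (single binary covariate, Breslow ties)
# ---------------------------------------------------------------------------

def cox_logrank(high, time, event, cutpoint=None, permutation_p=None,
                max_iter: int = 50, tol: float = 1e-10) -> SurvivalFit:
    """Cox fit (Newton on the Breslow partial likelihood) plus log-rank test.

    ``high`` is the binary group indicator (1 = high score).  The hazard
    ratio is exp(coef) for high versus low; the CI comes from the observed
    information.  Monotone likelihood (all events in one group) is flagged
    and the CI reported unbounded.  The log-rank test is computed
    independently of the Cox fit.
    """
    high = np.asarray(high).astype(bool)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if high.all() or (~high).all():
        raise ValueError("both groups must be nonempty")
    if event.sum() == 0:
        raise ValueError("no events observed")
    events_high = event[high].sum()
    events_low = event[~high].sum()
    separation = events_high == 0 or events_low == 0

    beta = 0.0
    x = high.astype(float)
    if not separation:
        for _ in range(max_iter):
            score, info = _breslow_score_info(beta, x, time, event)
            if info <= 0:
                break
            step = score / info
            beta += step
            if abs(step) < tol:
                break
        _, info = _breslow_score_info(beta, x, time, event)
        se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    else:
        beta = np.inf if events_low == 0 else -np.inf
        se = np.inf

    chi = float(logrank_chi2_stat(high, time, event))
    logrank_p = float(chi2.sf(chi, df=1))
    if np.isfinite(beta) and np.isfinite(se):
        wald_p = float(2 * norm.sf(abs(beta) / se)) if se > 0 else 0.0
        ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
        hr = float(np.exp(beta))
    else:
        wald_p = np.nan
        hr = float(np.exp(beta)) if beta != np.inf else np.inf
        ci = (0.0, np.inf)
    return SurvivalFit(
        cutpoint=cutpoint, n_high=int(high.sum()), n_low=int((~high).sum()),
        coef=float(beta), hazard_ratio=hr, ci_low=ci[0], ci_high=ci[1],
        wald_p=wald_p, logrank_chi2=chi, logrank_p=logrank_p,
        separation_flag=bool(separation), permutation_p=permutation_p,
    )


def _breslow_score_info(beta, x, time, event):
    """Score and information of the Breslow partial log-likelihood."""
    order = np.argsort(time, kind="stable")
    t, e, xv = time[order], event[order], x[order]
    w = np.exp(beta * xv)
    # suffix sums over the risk set
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xv)[::-1])[::-1]
    score = 0.0
    info = 0.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = e[i:j].sum()
        if d > 0:
            xbar = s1[i] / s0[i]
            score += (xv[i:j] * e[i:j]).sum() - d * xbar
            info += d * (xbar - xbar ** 2)  # x binary: E[x^2] = E[x]
        i = j
    return score, info


def breslow_loglik(beta, high, time, event):
    """Breslow partial log-likelihood (used by grid-search cross-checks)."""
    order = np.argsort(time, kind="stable")
    t = np.asarray(time, float)[order]
    e = np.asarray(event, int)[order]
    xv = np.asarray(high, float)[order]
    w = np.exp(beta * xv)
    s0 = np.cumsum(w[::-1])[::-1]
    ll = 0.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = e[i:j].sum()
        if d > 0:
            ll += beta * (xv[i:j] * e[i:j]).sum() - d * np.log(s0[i])
        i = j
    return float(ll)


def kaplan_meier(time, event):
    """Kaplan-Meier survival curve coordinates (time, at_risk, survival)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    surv = 1.0
    rows = [{"time": 0.0, "at_risk": len(time), "survival": 1.0}]
    n = len(time)
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d = event[i:j].sum()
        at_risk = n - i
        if d > 0:
            surv *= 1.0 - d / at_risk
            rows.append({"time": float(time[i]), "at_risk": int(at_risk),
                         "survival": float(surv)})
        i = j
    return pd.DataFrame(rows)
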