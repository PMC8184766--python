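"""Synthetic data generators emulating the statistical structure of the study.

Four generators cover the four data modalities the pipeline consumes:

* multi-lineage UMI counts with ~20-gene lineage programs (sorted-lineage
  reference stand-in),
* germinal-center cells whose gene programs are phase-shifted von Mises
  waves around a closed cycle,
* bulk cohort expression whose signature-gene level couples to a
  proportional-hazard survival outcome,
* spatial point patterns resembling tertiary lymphoid structures with or
  without a germinal center.

Every generator is a pure function of its parameters and seed and returns a
ground-truth object alongside the data.  UMI noise is negative binomial
parameterized by (mean, dispersion phi) with variance mean + mean^2/phi;
``dispersion=inf`` degenerates to Poisson.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special

from .io_config import ExpressionMatrix

TARGET_MEDIAN_DEPTH = 3000.0  # UMIs per cell, 10x-like

# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LineageSimTruth:
    labels: np.ndarray            # per-cell lineage name
    programs: dict                # lineage -> list of program gene ids
    fold: float
    baseline_means: np.ndarray    # per-gene baseline mean
    dispersion: float


@dataclasses.dataclass
class CycleSimTruth:
    theta: np.ndarray             # per-cell true phase in [0, 1)
    programs: dict                # program name -> gene ids
    centers: np.ndarray           # program phase centers phi_p
    kappa: float
    phase_bin: np.ndarray         # per-cell bin index in 0..n_bins-1


@dataclasses.dataclass
class CohortSimTruth:
    latent: np.ndarray            # per-patient latent score s
    signature: list               # signature gene ids
    coupling: float
    beta: float
    censor_frac: float


@dataclasses.dataclass
class SpatialSimTruth:
    table: pd.DataFrame           # cell_id, x, y, cell_type
    pattern: str


# ---------------------------------------------------------------------------
# Shared noise model
# ---------------------------------------------------------------------------

def _nb_sample(rng, mean, dispersion):
    """Negative binomial with variance mean + mean^2/dispersion (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if np.isinf(dispersion):
        return rng.poisson(mean)
    if dispersion <= 0:
        raise ValueError(f"dispersion must be > 0, got {dispersion}")
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-300) / dispersion)
    return rng.poisson(lam)


def _baseline_means(rng, n_genes):
    """Log-normal baseline gene means rescaled to a 10x-like median depth."""
    means = rng.lognormal(mean=-1.0, sigma=1.0, size=n_genes)
    return means * (TARGET_MEDIAN_DEPTH / means.sum())


def _ids(prefix, n):
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_lineage_counts(n_lineages, cells_per_lineage, n_genes,
                       program_size=20, fold=2.0, dispersion=2.0, seed=0):
    """Simulate sorted-lineage-like UMI counts with disjoint marker programs.

    Cells of lineage L have the means of L's ``program_size`` program genes
    multiplied by ``fold``; all counts are negative binomial around the
    (possibly boosted) means.

    Returns ``(ExpressionMatrix, LineageSimTruth)``.
    """
    if n_genes < n_lineages * program_size:
        raise ValueError(
            f"n_genes={n_genes} < n_lineages*program_size="
            f"{n_lineages * program_size}"
        )
    if fold <= 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    rng = np.random.default_rng(seed)
    gene_ids = _ids("g", n_genes)
    n_cells = n_lineages * cells_per_lineage
    cell_ids = _ids("cell", n_cells)

    base = _baseline_means(rng, n_genes)
    perm = rng.permutation(n_genes)
    programs = {}
    for li in range(n_lineages):
        idx = perm[li * program_size:(li + 1) * program_size]
        programs[f"L{li + 1}"] = [gene_ids[j] for j in idx]

    labels = np.repeat([f"L{li + 1}" for li in range(n_lineages)],
                       cells_per_lineage)
    means = np.tile(base, (n_cells, 1))
    lookup = {g: j for j, g in enumerate(gene_ids)}
    for lineage, genes in programs.items():
        cols = [lookup[g] for g in genes]
        rows = labels == lineage
        means[np.ix_(rows, cols)] *= fold

    counts = _nb_sample(rng, means, dispersion)
    m = ExpressionMatrix(cell_ids, gene_ids, counts)
    truth = LineageSimTruth(labels=labels, programs=programs, fold=fold,
                            baseline_means=base, dispersion=dispersion)
    return m, truth


def gen_gc_cycle(n_cells, n_genes, n_programs=3, kappa=2.0, n_bins=6,
                 dispersion=2.0, program_size=20, seed=0):
    """Simulate cells on a transcriptional cycle with phase-shifted waves.

    Cell phases theta are uniform on [0, 1); program-p gene means are scaled
    by the von Mises-shaped wave exp(kappa*cos(2*pi*(theta - phi_p)))/I0(kappa)
    whose circular mean multiplier is 1.  Program centers phi_p are equally
    spaced on [0, 1).

    Returns ``(ExpressionMatrix, CycleSimTruth)``.
    """
    if n_programs < 2:
        raise ValueError("n_programs must be >= 2")
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    if n_genes < n_programs * program_size:
        raise ValueError("n_genes too small for the requested programs")
    rng = np.random.default_rng(seed)
    gene_ids = _ids("g", n_genes)
    cell_ids = _ids("cell", n_cells)

    base = _baseline_means(rng, n_genes)
    perm = rng.permutation(n_genes)
    # waves should ride on decently expressed genes: floor program baselines
    # at the median baseline so low-count dropout does not drown the signal
    floor = np.median(base)
    centers = np.arange(n_programs) / n_programs
    programs = {}
    program_cols = {}
    for p in range(n_programs):
        idx = perm[p * program_size:(p + 1) * program_size]
        base[idx] = np.maximum(base[idx], floor)
        programs[f"P{p + 1}"] = [gene_ids[j] for j in idx]
        program_cols[p] = idx

    theta = rng.uniform(0.0, 1.0, size=n_cells)
    means = np.tile(base, (n_cells, 1))
    i0 = scipy.special.i0(kappa)
    for p in range(n_programs):
        wave = np.exp(kappa * np.cos(2 * np.pi * (theta - centers[p]))) / i0
        means[:, program_cols[p]] *= wave[:, None]

    counts = _nb_sample(rng, means, dispersion)
    m = ExpressionMatrix(cell_ids, gene_ids, counts)
    phase_bin = np.minimum((theta * n_bins).astype(int), n_bins - 1)
    truth = CycleSimTruth(theta=theta, programs=programs, centers=centers,
                          kappa=kappa, phase_bin=phase_bin)
    return m, truth


def gen_bulk_survival(n_patients, n_genes=500, signature_size=50,
                      coupling=1.0, beta=0.7, censor_frac=0.3, seed=0,
                      baseline_rate=0.1):
    """Simulate a bulk-expression cohort with survival coupled to a latent score.

    Per patient i, latent s_i ~ N(0, 1); signature-gene expression is
    baseline + coupling*s_i + noise; event times are exponential with rate
    baseline_rate * exp(beta * s_i); censoring is independent and calibrated
    so the expected censored fraction equals ``censor_frac``.

    Returns ``(patient x gene DataFrame, survival DataFrame, CohortSimTruth)``.
    """
    if not 0 <= censor_frac < 1:
        raise ValueError(f"censor_frac must be in [0, 1), got {censor_frac}")
    if signature_size >= n_genes:
        raise ValueError("signature_size must be < n_genes")
    rng = np.random.default_rng(seed)
    gene_ids = _ids("g", n_genes)
    patient_ids = _ids("pt", n_patients)

    s = rng.normal(0.0, 1.0, size=n_patients)
    baseline = rng.normal(5.0, 2.0, size=n_genes)
    expr = baseline[None, :] + rng.normal(0.0, 1.0, size=(n_patients, n_genes))
    sig_idx = rng.choice(n_genes, size=signature_size, replace=False)
    expr[:, sig_idx] += coupling * s[:, None]
    signature = [gene_ids[j] for j in sorted(sig_idx)]

    rates = baseline_rate * np.exp(beta * s)
    t_event = rng.exponential(1.0 / rates)
    if censor_frac > 0:
        rc = _calibrate_censor_rate(rates, censor_frac)
        t_cens = rng.exponential(1.0 / rc, size=n_patients)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n_patients, dtype=int)

    expr_df = pd.DataFrame(expr, index=pd.Index(patient_ids, name="patient_id"),
                           columns=gene_ids)
    surv_df = pd.DataFrame({"patient_id": patient_ids, "time": time,
                            "event": event})
    truth = CohortSimTruth(latent=s, signature=signature, coupling=coupling,
                           beta=beta, censor_frac=censor_frac)
    return expr_df, surv_df, truth


def _calibrate_censor_rate(event_rates, censor_frac):
    """Exponential censor rate whose marginal censor probability hits the target.

    With competing exponentials, P(censored | rate lam) = rc / (rc + lam);
    solve mean over patients = censor_frac.
    """
    def mean_censored(rc):
        return float(np.mean(rc / (rc + event_rates))) - censor_frac

    hi = event_rates.max() * censor_frac / (1 - censor_frac) * 10 + 1.0
    return scipy.optimize.brentq(mean_censored, 1e-12, hi)


_SPATIAL_PATTERNS = ("mixed", "segregated", "tls_gc", "tls_nogc")


def gen_spatial_map(pattern, n_cells, type_props=None, seed=0):
    """Simulate a segmented-cell spatial map.

    Patterns: ``mixed`` (uniform positions, i.i.d. labels), ``segregated``
    (one Gaussian blob per type, centers >= 6 blob SDs apart), ``tls_gc``
    (central B-cell disc, CD4 ring, sparse others — an idealized tertiary
    lymphoid structure with germinal center), ``tls_nogc`` (B cells dispersed
    among CD8/Treg).  Coordinates are in arbitrary units.

    Returns :class:`SpatialSimTruth`.
    """
    if pattern not in _SPATIAL_PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; use one of {_SPATIAL_PATTERNS}")
    if n_cells < 3:
        raise ValueError("need at least 3 cells for triangulation")
    rng = np.random.default_rng(seed)
    if type_props is None:
        type_props = {
            "mixed": {"B": 0.5, "CD4": 0.5},
            "segregated": {"B": 0.5, "CD8": 0.5},
            "tls_gc": {"B": 0.4, "CD4": 0.3, "CD8": 0.2, "Treg": 0.1},
            "tls_nogc": {"B": 0.3, "CD8": 0.4, "Treg": 0.3},
        }[pattern]
    names = list(type_props)
    props = np.array([type_props[t] for t in names], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("type proportions must sum to 1")
    if len(names) < 2:
        raise ValueError("interaction patterns need >= 2 cell types")

    # largest-remainder apportionment keeps counts exact and deterministic
    counts = np.floor(props * n_cells).astype(int)
    rem = n_cells - counts.sum()
    order = np.argsort(-(props * n_cells - counts))
    counts[order[:rem]] += 1
    types = np.repeat(names, counts)

    field = 1000.0
    if pattern == "mixed" or pattern == "tls_nogc":
        xy = rng.uniform(0, field, size=(n_cells, 2))
        types = rng.permutation(types)
    elif pattern == "segregated":
        sd = 30.0
        k = len(names)
        radius = max(3 * sd * k / np.pi, 6 * sd)  # chord spacing >= 6 SDs
        angles = 2 * np.pi * np.arange(k) / k
        centers = field / 2 + radius * np.c_[np.cos(angles), np.sin(angles)]
        xy = np.vstack([
            centers[i] + rng.normal(0, sd, size=(counts[i], 2))
            for i in range(k)
        ])
    else:  # tls_gc
        xy = np.empty((n_cells, 2))
        center = np.array([field / 2, field / 2])
        r_disc, r_in, r_out = 100.0, 120.0, 200.0
        pos = 0
        for name, cnt in zip(names, counts):
            if name == "B":
                r = r_disc * np.sqrt(rng.uniform(0, 1, cnt))
                a = rng.uniform(0, 2 * np.pi, cnt)
                xy[pos:pos + cnt] = center + np.c_[r * np.cos(a), r * np.sin(a)]
            elif name == "CD4":
                r = np.sqrt(rng.uniform(r_in ** 2, r_out ** 2, cnt))
                a = rng.uniform(0, 2 * np.pi, cnt)
                xy[pos:pos + cnt] = center + np.c_[r * np.cos(a), r * np.sin(a)]
            else:
                xy[pos:pos + cnt] = rng.uniform(0, field, size=(cnt, 2))
            pos += cnt

    table = pd.DataFrame({
        "cell_id": _ids("c", n_cells),
        "x": xy[:, 0],
        "y": xy[:, 1],
        "cell_type": types,
    })
    return SpatialSimTruth(table=table, pattern=pattern)
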