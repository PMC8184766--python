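import numpy as np
import pandas as pd
import pytest

from tilbkit import survival as sv
from tilbkit import synthetic_data as sd


class TestDeriveSignatures:
    def _markers(self, logfcs, cluster=1):
        return pd.DataFrame({"gene": list(logfcs), "cluster": cluster,
                             "logfc": list(logfcs.values()),
                             "p": 0.01, "p_adj": 0.05})

    def test_threshold_semantics_empty_is_error(self):
        markers = self._markers({"g1": 0.4, "g2": 0.3})
        with pytest.raises(ValueError, match="threshold"):
            sv.derive_signatures(markers, mode="lineage", lfc_threshold=0.5)

    def test_top_n_by_logfc(self):
        markers = self._markers({"g1": 2.0, "g2": 1.5, "g3": 1.0, "g4": 0.5})
        sig = sv.derive_signatures(markers, mode="cluster_top", top_n=3)
        assert sig.genes == ["g1", "g2", "g3"]

    def test_recall_of_true_program_genes(self):
        from tilbkit import enrichment as en
        from tilbkit import preprocess as pp
        m, truth = sd.gen_lineage_counts(3, 100, 200, fold=4.0, seed=51)
        pp.normalize_log(m)
        lineages = sorted(truth.programs)
        clusters = np.array([lineages.index(l) + 1 for l in truth.labels])
        markers = en.cluster_markers(m, clusters)
        sig = sv.derive_signatures(markers, mode="lineage",
                                   target_clusters=[1], lfc_threshold=0.5)
        recall = len(set(sig.genes) & set(truth.programs[lineages[0]])) / 20
        assert recall >= 0.9


class TestKsEnrichmentScore:
    def _expr(self, values, genes):
        return pd.DataFrame([values], index=pd.Index(["p1"], name="patient_id"),
                            columns=genes)

    def test_maximal_separation(self):
        # signature genes occupy the top ranks -> D = +1
        expr = self._expr([10, 9, 8, 1, 2, 3], list("abcdef"))
        out = sv.ks_enrichment_score(expr, sv.Signature("s", ["a", "b", "c"]))
        assert out.loc[0, "D"] == pytest.approx(1.0)

    def test_alternating_interleaving_gives_small_d(self):
        # 10 genes perfectly alternating in/out -> D = 0.2
        genes = [f"g{i}" for i in range(10)]
        values = list(range(10, 0, -1))
        sig = sv.Signature("s", genes[0::2])
        out = sv.ks_enrichment_score(self._expr(values, genes), sig)
        assert abs(out.loc[0, "D"]) == pytest.approx(0.2)

    def test_signed_antisymmetry_exact(self, rng):
        genes = [f"g{i}" for i in range(40)]
        expr = pd.DataFrame(rng.normal(size=(5, 40)),
                            index=[f"p{i}" for i in range(5)], columns=genes)
        inside = sv.Signature("in", genes[:15])
        outside = sv.Signature("out", genes[15:])
        d_in = sv.ks_enrichment_score(expr, inside)["D"].to_numpy()
        d_out = sv.ks_enrichment_score(expr, outside)["D"].to_numpy()
        assert np.allclose(d_in, -d_out)

    def test_monotone_transform_invariance(self, rng):
        genes = [f"g{i}" for i in range(30)]
        vals = rng.normal(size=(4, 30))
        sig = sv.Signature("s", genes[:10])
        d1 = sv.ks_enrichment_score(
            pd.DataFrame(vals, columns=genes), sig)["D"]
        d2 = sv.ks_enrichment_score(
            pd.DataFrame(np.exp(vals) + 3, columns=genes), sig)["D"]
        assert np.allclose(d1, d2)

    def test_signature_covering_all_genes_rejected(self):
        genes = [f"g{i}" for i in range(5)]
        expr = self._expr(range(5), genes)
        with pytest.raises(ValueError):
            sv.ks_enrichment_score(expr, sv.Signature("s", genes))

    def test_score_tracks_latent_when_coupled(self):
        expr, _, truth = sd.gen_bulk_survival(300, 500, 50, coupling=1.0,
                                              seed=52)
        scores = sv.ks_enrichment_score(expr, sv.Signature("s", truth.signature))
        assert np.corrcoef(scores["D"], truth.latent)[0, 1] >= 0.7


class TestOptimalCutpoint:
    def test_planted_separation_found(self, rng):
        n = 80
        scores = np.r_[rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n // 2)]
        rate = np.where(scores > 0, 10.0, 0.1)
        time = rng.exponential(1 / rate)
        event = np.ones(n, dtype=int)
        out = sv.optimal_cutpoint(scores, time, event, n_perm=0)
        assert -2 < out["cutpoint"] < 2

    def test_min_frac_infeasible_rejected(self, rng):
        scores = rng.normal(size=11)
        time = rng.exponential(1, 11)
        with pytest.raises(ValueError):
            sv.optimal_cutpoint(scores, time, np.ones(11, int), min_frac=0.5)

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValueError):
            sv.optimal_cutpoint(np.ones(20), rng.exponential(1, 20),
                                np.ones(20, int))

    def test_null_optimized_p_is_anticonservative_but_permutation_p_is_not(self):
        # cutpoint optimization inflates the nominal log-rank p; the
        # permutation-adjusted p stays honest
        rng = np.random.default_rng(99)
        nominal = perm = 0
        reps = 40
        for _ in range(reps):
            scores = rng.normal(size=60)
            time = rng.exponential(1, 60)
            event = rng.integers(0, 2, 60)
            if event.sum() < 5:
                event[:5] = 1
            out = sv.optimal_cutpoint(scores, time, event, n_perm=99,
                                      seed=int(rng.integers(2**31)))
            nominal += out["p_nominal"] < 0.05
            perm += out["p_permutation"] < 0.05
        assert nominal / reps > 0.05
        assert perm / reps <= 0.15


class TestCoxLogrank:
    def test_agrees_with_lifelines_on_continuous_free_data(self, rng):
        from lifelines import CoxPHFitter
        from lifelines.statistics import logrank_test
        n = 120
        high = rng.integers(0, 2, n).astype(bool)
        time = rng.exponential(np.where(high, 0.5, 1.0))
        event = rng.integers(0, 2, n)
        event[:10] = 1
        fit = sv.cox_logrank(high, time, event)
        df = pd.DataFrame({"x": high.astype(float), "time": time,
                           "event": event})
        ll = CoxPHFitter().fit(df, "time", "event")
        # continuous times -> no ties -> Breslow == Efron
        assert fit.coef == pytest.approx(float(ll.params_["x"]), abs=1e-5)
        lr = logrank_test(time[high], time[~high], event[high], event[~high])
        assert fit.logrank_chi2 == pytest.approx(lr.test_statistic, rel=1e-6)

    def test_newton_matches_gridsearch_optimum(self, rng):
        _, surv, truth = sd.gen_bulk_survival(400, 50, 10, beta=0.7, seed=53)
        high = truth.latent > np.median(truth.latent)
        fit = sv.cox_logrank(high, surv["time"], surv["event"])
        grid = np.arange(fit.coef - 0.02, fit.coef + 0.02, 1e-5)
        lls = [sv.breslow_loglik(b, high, surv["time"], surv["event"])
               for b in grid]
        assert abs(grid[int(np.argmax(lls))] - fit.coef) <= 1e-4

    def test_null_ci_covers_one(self):
        covered = 0
        for rep in range(20):
            _, surv, truth = sd.gen_bulk_survival(400, 20, 5, beta=0.0,
                                                  seed=500 + rep)
            high = truth.latent > np.median(truth.latent)
            fit = sv.cox_logrank(high, surv["time"], surv["event"])
            covered += fit.ci_low <= 1.0 <= fit.ci_high
        assert covered >= 18

    def test_separation_flagged_with_unbounded_ci(self):
        time = np.r_[np.ones(10), 2 * np.ones(10)]
        event = np.r_[np.ones(10, int), np.zeros(10, int)]
        high = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        fit = sv.cox_logrank(high, time, event)
        assert fit.separation_flag
        assert fit.ci_high == np.inf

    def test_degenerate_inputs_rejected(self, rng):
        time = rng.exponential(1, 10)
        with pytest.raises(ValueError):
            sv.cox_logrank(np.ones(10, bool), time, np.ones(10, int))
        with pytest.raises(ValueError):
            sv.cox_logrank(np.r_[np.ones(5, bool), np.zeros(5, bool)], time,
                           np.zeros(10, int))


def test_kaplan_meier_steps_down_at_events():
    km = sv.kaplan_meier([1, 2, 3, 4], [1, 0, 1, 1])
    assert km["survival"].iloc[0] == 1.0
    assert (np.diff(km["survival"]) < 0).all()
    assert km["survival"].iloc[-1] == pytest.approx(0.0)
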