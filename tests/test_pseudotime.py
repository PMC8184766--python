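import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from conftest import lognorm_matrix
from tilbkit import preprocess as pp
from tilbkit import pseudotime as pt
from tilbkit import synthetic_data as sd


def embedding(coords, kind="diffusion"):
    coords = np.asarray(coords, dtype=float)
    spectrum = np.linspace(1.0, 0.5, coords.shape[1])
    return pp.EmbeddingResult(kind, coords, spectrum,
                              [f"c{i}" for i in range(coords.shape[0])])


@pytest.fixture(scope="module")
def gc_pipeline():
    """Shared end-to-end cyclical pipeline on one generated cycle."""
    m, truth = sd.gen_gc_cycle(600, 500, n_programs=3, kappa=2.0, seed=5)
    pp.normalize_log(m)
    hvg = pp.select_hvg(m, 200)
    covars = pp.compute_technical_covariates(m)
    pca = pp.embed_pca(m, hvg, covars, n_pc=20)
    dmap = pp.diffusion_map(pca, n_dc=10, kernel_k=30)
    clusters = pp.cluster_graph(dmap, k_neighbors=20, seed=3)
    pair, _ = pt.select_circular_components(dmap)
    cpt = pt.fit_cyclical_pseudotime(dmap, clusters, pair)
    return m, truth, cpt


class TestLinearPseudotime:
    def test_collinear_blobs_order_along_path(self, rng):
        blobs = [rng.normal([c, 0], 0.1, size=(30, 2)) for c in (0, 5, 10)]
        e = embedding(np.vstack(blobs))
        clusters = np.repeat(["A", "B", "C"], 30)
        lp = pt.fit_linear_pseudotime(e, clusters, start="A", end="C")
        means = [np.nanmean(lp.t[clusters == k]) for k in "ABC"]
        assert means[0] < means[1] < means[2]
        assert lp.path == ["A", "B", "C"]

    def test_start_equals_end_rejected(self, rng):
        e = embedding(rng.normal(size=(20, 2)))
        with pytest.raises(ValueError):
            pt.fit_linear_pseudotime(e, [1] * 10 + [2] * 10, 1, 1)

    def test_off_path_cells_get_nan(self, rng):
        blobs = [rng.normal([c, 0], 0.1, size=(20, 2)) for c in (0, 5)]
        stray = rng.normal([2.5, 40], 0.1, size=(20, 2))
        e = embedding(np.vstack(blobs + [stray]))
        clusters = np.repeat(["A", "B", "Z"], 20)
        lp = pt.fit_linear_pseudotime(e, clusters, "A", "B")
        assert np.isnan(lp.t[clusters == "Z"]).all()

    def test_recovers_latent_progression(self, rng):
        # two-segment path with a latent progression variable
        u = np.sort(rng.uniform(0, 2, 150))
        xy = np.where(u[:, None] < 1,
                      np.c_[u, np.zeros_like(u)],
                      np.c_[np.ones_like(u), u - 1])
        xy = xy + rng.normal(0, 0.02, xy.shape)
        clusters = np.digitize(u, [0.67, 1.33]) + 1
        e = embedding(xy)
        lp = pt.fit_linear_pseudotime(e, clusters, 1, 3)
        rho = spearmanr(lp.t, u).statistic
        assert rho >= 0.9


class TestSelectCircularComponents:
    def test_planted_circle_found(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 300)
        coords = rng.normal(0, 0.05, size=(300, 5))
        coords[:, 0] += np.cos(theta)
        coords[:, 2] += np.sin(theta)
        pair, score = pt.select_circular_components(embedding(coords))
        assert pair == (0, 2)
        assert score > pt.CONFIDENT_CIRCULARITY

    def test_gaussian_blob_scores_below_confident(self, rng):
        coords = rng.normal(size=(2000, 5))
        pair, score = pt.select_circular_components(embedding(coords))
        # radius CV of a 2D gaussian is ~0.52, so score ~0.48
        assert 0.3 < score < pt.CONFIDENT_CIRCULARITY
        assert score == pytest.approx(0.48, abs=0.05)

    def test_override_honored(self, rng):
        coords = rng.normal(size=(100, 5))
        pair, score = pt.select_circular_components(embedding(coords),
                                                    override=(2, 4))
        assert pair == (2, 4)
        assert np.isfinite(score)


class TestCyclicalPseudotime:
    def _unit_circle(self, n=300):
        theta = (np.arange(n) + 0.5) / n
        xy = np.c_[np.cos(2 * np.pi * theta), np.sin(2 * np.pi * theta)]
        clusters = np.minimum((theta * 6).astype(int) + 1, 6)
        return theta, embedding(xy), clusters

    def test_noiseless_circle_recovered_exactly(self):
        theta, e, clusters = self._unit_circle()
        cpt = pt.fit_cyclical_pseudotime(e, clusters, (0, 1))
        aligned, _ = pt.align_phases(cpt.phase, theta)
        assert pt.circular_correlation(aligned, theta) >= 1.0 - 1e-6

    def test_ring_visits_sextants_in_angular_order(self):
        _, e, clusters = self._unit_circle()
        cpt = pt.fit_cyclical_pseudotime(e, clusters, (0, 1))
        ring = cpt.ring
        assert sorted(ring) == [1, 2, 3, 4, 5, 6]
        start = ring.index(1)
        rolled = ring[start:] + ring[:start]
        assert rolled == [1, 2, 3, 4, 5, 6] or rolled == [1, 6, 5, 4, 3, 2]

    def test_rotation_equivariance(self):
        theta, e, clusters = self._unit_circle()
        cpt1 = pt.fit_cyclical_pseudotime(e, clusters, (0, 1))
        ang = 1.1
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        e2 = embedding(e.coordinates @ rot.T)
        cpt2 = pt.fit_cyclical_pseudotime(e2, clusters, (0, 1))
        assert abs(pt.circular_correlation(cpt1.phase, cpt2.phase)) >= 1 - 1e-6

    def test_too_few_clusters_rejected(self, rng):
        e = embedding(rng.normal(size=(30, 2)))
        with pytest.raises(ValueError):
            pt.fit_cyclical_pseudotime(e, [1] * 15 + [2] * 15, (0, 1))

    def test_generated_cycle_recovered(self, gc_pipeline):
        m, truth, cpt = gc_pipeline
        aligned, _ = pt.align_phases(cpt.phase, truth.theta)
        assert pt.circular_correlation(aligned, truth.theta) >= 0.9


class TestGeneDynamics:
    def test_constant_gene_flat_fit(self, gc_pipeline):
        m, truth, cpt = gc_pipeline
        m2 = lognorm_matrix(np.column_stack([
            np.full(m.n_cells, 2.0), m.lognorm[:, 0]]), gene_prefix="x")
        dyn = pt.fit_gene_dynamics(m2, cpt, ["x0"])
        assert dyn.amplitude[0] == 0.0

    def test_periodicity_of_cyclical_fit(self, gc_pipeline):
        m, truth, cpt = gc_pipeline
        genes = truth.programs["P1"][:5]
        dyn = pt.fit_gene_dynamics(m, cpt, genes)
        # evaluate the fit on a grid point approaching 1 (wrap-around)
        from tilbkit.pseudotime import _periodic_loess
        idx = m.gene_index(genes[:1])
        z = m.lognorm[:, idx[0]]
        z = (z - z.mean()) / z.std()
        at0, at1 = _periodic_loess(cpt.phase, z, np.array([0.0, 1.0 - 1e-9]),
                                   span=0.3)
        assert abs(at0 - at1) < 1e-6

    def test_kappa_zero_gives_small_amplitudes(self):
        m, truth = sd.gen_gc_cycle(500, 300, kappa=0.0, seed=6)
        pp.normalize_log(m)
        phases = pt.CyclicalPseudotime(
            phase=truth.theta, pair=(0, 1), ring=[1], curve=np.zeros((2, 2)),
            convention={}, cell_ids=list(m.cell_ids))
        genes = [g for prog in truth.programs.values() for g in prog]
        dyn = pt.fit_gene_dynamics(m, phases, genes)
        assert np.median(dyn.amplitude) < 0.3
        assert dyn.amplitude.max() < 0.8

    def test_peak_phase_matches_program_center(self, gc_pipeline):
        m, truth, cpt = gc_pipeline
        aligned, reflected = pt.align_phases(cpt.phase, truth.theta)
        pt_aligned = pt.CyclicalPseudotime(
            phase=aligned, pair=cpt.pair, ring=cpt.ring, curve=cpt.curve,
            convention=cpt.convention, cell_ids=cpt.cell_ids)
        for p, (name, genes) in enumerate(truth.programs.items()):
            dyn = pt.fit_gene_dynamics(m, pt_aligned, genes)
            diffs = np.abs(dyn.peak_phase - truth.centers[p])
            circ = np.minimum(diffs, 1 - diffs)
            assert np.median(circ) <= 0.1

    def test_absent_gene_rejected(self, gc_pipeline):
        m, truth, cpt = gc_pipeline
        with pytest.raises(ValueError, match="missing_gene"):
            pt.fit_gene_dynamics(m, cpt, ["missing_gene"])


class TestWaveClustering:
    def _dynamics(self, curves, cyclical=True):
        curves = np.asarray(curves, dtype=float)
        grid = np.arange(curves.shape[1]) / curves.shape[1]
        return pt.GeneDynamics(
            genes=[f"g{i}" for i in range(curves.shape[0])], grid=grid,
            curves=curves, amplitude=curves.max(1) - curves.min(1),
            peak_phase=grid[curves.argmax(1)], cyclical=cyclical)

    def test_identical_pair_plus_antiphase_gives_two_waves(self):
        t = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        d = self._dynamics([np.sin(t), np.sin(t), -np.sin(t)])
        waves = pt.cluster_gene_waves(d, k="auto")
        assert len(np.unique(waves)) == 2
        assert waves[0] == waves[1] != waves[2]

    def test_three_program_waves_recovered(self, gc_pipeline):
        m, truth, cpt = gc_pipeline
        genes = [g for prog in truth.programs.values() for g in prog]
        labels = [name for name, prog in truth.programs.items() for _ in prog]
        dyn = pt.fit_gene_dynamics(m, cpt, genes)
        waves = pt.cluster_gene_waves(dyn, k="auto")
        assert len(np.unique(waves)) == 3
        assert adjusted_rand_score(labels, waves) >= 0.9

    def test_duplication_leaves_clustering_unchanged(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        curves = [np.sin(t), np.cos(t), np.sin(t + 3)]
        w1 = pt.cluster_gene_waves(self._dynamics(curves), k=3)
        w2 = pt.cluster_gene_waves(self._dynamics(curves + curves), k=3)
        assert (w2[:3] == w2[3:]).all()
        assert adjusted_rand_score(w1, w2[:3]) == 1.0

    def test_flat_curves_rejected(self):
        d = self._dynamics(np.ones((3, 20)))
        with pytest.raises(ValueError):
            pt.cluster_gene_waves(d)


class TestAnchorDynamics:
    def _dyn(self):
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        curves = [np.sin(t), np.sin(t), -np.sin(t), np.cos(t)]
        grid = np.arange(60) / 60
        return pt.GeneDynamics(
            genes=["anchor", "twin", "anti", "quarter"], grid=grid,
            curves=np.asarray(curves),
            amplitude=np.array([2.0, 2.0, 2.0, 2.0]),
            peak_phase=np.zeros(4), cyclical=True)

    def test_identical_gene_ranks_first(self):
        out = pt.anchor_dynamics(self._dyn(), "anchor", top_k=2)
        assert out.iloc[0]["gene"] == "twin"
        assert out.iloc[0]["correlation"] == pytest.approx(1.0)

    def test_antiphase_gene_excluded_from_top(self):
        out = pt.anchor_dynamics(self._dyn(), "anchor", top_k=2)
        assert "anti" not in set(out["gene"])
        assert "anchor" not in set(out["gene"])

    def test_program_mates_share_anchor_dynamics(self, gc_pipeline):
        m, truth, cpt = gc_pipeline
        genes = [g for prog in truth.programs.values() for g in prog]
        dyn = pt.fit_gene_dynamics(m, cpt, genes)
        anchor = truth.programs["P1"][0]
        out = pt.anchor_dynamics(dyn, anchor, top_k=19)
        frac = np.mean([g in set(truth.programs["P1"]) for g in out["gene"]])
        assert frac >= 0.8

    def test_flat_anchor_rejected(self):
        d = self._dyn()
        d.amplitude[0] = 0.0
        with pytest.raises(ValueError):
            pt.anchor_dynamics(d, "anchor")
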