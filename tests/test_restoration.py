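import numpy as np
import pytest

from mitodetect.imaging_model import apply_psf, make_psf, psf_to_dense
from mitodetect.restoration import (
    RestorationConfig,
    build_similarity_graph,
    preprocess_frame,
    restoration_objective,
    restore,
)

from _oracles import similarity_graph_bruteforce


def _trace_is_monotone(trace, rel_slack=1e-8):
    t = np.asarray(trace)
    return bool(np.all(np.diff(t) <= rel_slack * np.maximum(np.abs(t[:-1]), 1.0)))


class TestSimilarityGraph:
    def test_constant_image_unit_weights(self):
        g = build_similarity_graph(np.full((4, 4), 2.0), "4-connected")
        assert np.allclose(g.weights.data, 1.0)
        rowsums = np.asarray(g.laplacian.sum(axis=1)).ravel()
        np.testing.assert_allclose(rowsums, 0.0, atol=1e-10)

    def test_laplacian_annihilates_constants(self, rng):
        g = build_similarity_graph(rng.normal(size=(6, 6)), "8-connected")
        f = np.full(36, 3.3)
        assert abs(g.quad_form(f)) < 1e-10

    def test_quad_form_positive_semidefinite(self, rng):
        g = build_similarity_graph(rng.normal(size=(5, 7)), "8-connected")
        for _ in range(20):
            assert g.quad_form(rng.normal(size=35)) >= -1e-10

    @pytest.mark.parametrize("neighborhood", ["4-connected", "8-connected"])
    def test_matches_exhaustive_pair_oracle(self, neighborhood):
        img = np.array([[0.0, 1.0], [2.0, 3.0]])
        g = build_similarity_graph(img, neighborhood)
        sigma1, W, L = similarity_graph_bruteforce(img, neighborhood)
        assert g.sigma1 == pytest.approx(sigma1, abs=1e-12)
        np.testing.assert_allclose(g.weights.toarray(), W, atol=1e-12)
        np.testing.assert_allclose(g.laplacian.toarray(), L, atol=1e-12)

    def test_single_pixel_rejected(self):
        with pytest.raises(ValueError):
            build_similarity_graph(np.ones((1, 1)))


class TestRestorationObjective:
    def test_zero_everything(self, small_psf):
        z = np.zeros((4, 4))
        graph = build_similarity_graph(np.arange(16.0).reshape(4, 4))
        cfg = RestorationConfig()
        assert restoration_objective(z, z, small_psf, graph, cfg) == 0.0

    def test_zero_f_leaves_fidelity(self, small_psf, rng):
        g = rng.normal(size=(4, 4))
        graph = build_similarity_graph(g)
        cfg = RestorationConfig()
        val = restoration_objective(np.zeros((4, 4)), g, small_psf, graph, cfg, "normal")
        assert val == pytest.approx(float((g**2).sum()), rel=1e-12)

    def test_matches_dense_matrix_oracle(self, small_psf, rng):
        g = rng.normal(size=(8, 8))
        f = np.abs(rng.normal(size=(8, 8)))
        graph = build_similarity_graph(g)
        cfg = RestorationConfig(w_smooth=0.7, w_sparse=0.3)
        reweight = np.abs(rng.normal(size=64)) + 0.1
        for sign, s in (("normal", -1.0), ("mitotic", +1.0)):
            got = restoration_objective(f, g, small_psf, graph, cfg, sign, reweight)
            P = psf_to_dense(small_psf, (8, 8))
            L = graph.laplacian.toarray()
            fv, gv = f.ravel(), g.ravel()
            resid = P @ fv + s * gv
            expected = (
                float(resid @ resid)
                + cfg.w_smooth * float(fv @ L @ fv)
                + cfg.w_sparse * float(np.abs(reweight * fv).sum())
            )
            assert got == pytest.approx(expected, rel=1e-9)

    def test_negative_f_rejected(self, small_psf, rng):
        g = rng.normal(size=(4, 4))
        graph = build_similarity_graph(g)
        f = np.zeros((4, 4))
        f[0, 0] = -0.5
        with pytest.raises(ValueError):
            restoration_objective(f, g, small_psf, graph, RestorationConfig())


class TestPreprocess:
    def test_range_and_centering(self, rng):
        g = rng.normal(10.0, 3.0, size=(8, 8))
        p = preprocess_frame(g)
        assert abs(float(np.median(p))) < 1e-12
        assert p.max() - p.min() == pytest.approx(1.0, abs=1e-12)

    def test_constant_frame_maps_to_zero(self):
        np.testing.assert_array_equal(preprocess_frame(np.full((5, 5), 9.0)), 0.0)


class TestRestore:
    def test_zero_image_restores_to_zero(self, small_psf):
        res = restore(np.zeros((8, 8)), small_psf, sign="normal")
        assert res.restored.max() == 0.0

    def test_iterates_nonnegative_and_trace_monotone(self, small_psf, rng):
        g = rng.normal(0.5, 0.2, size=(12, 12))
        res = restore(g, small_psf, sign="mitotic")
        assert np.all(res.restored >= 0)
        assert _trace_is_monotone(res.objective_trace)

    def test_sign_flip_identity(self, small_psf, rng):
        g = rng.normal(0.5, 0.2, size=(10, 10))
        mito = restore(g, small_psf, sign="mitotic")
        norm = restore(-g, small_psf, sign="normal")
        np.testing.assert_allclose(mito.restored, norm.restored, atol=1e-9)

    def test_recovers_block_support(self, small_psf, rng):
        f_true = np.zeros((12, 12))
        f_true[2:4, 2:4] = 1.0
        f_true[8:10, 8:10] = 1.0
        g = apply_psf(f_true, small_psf) + rng.normal(0, 0.01, size=(12, 12))
        res = restore(g, small_psf, sign="normal")
        support = res.restored > 0.1 * res.restored.max()
        truth = f_true > 0
        jaccard = (support & truth).sum() / (support | truth).sum()
        assert jaccard >= 0.8

    def test_background_suppression_on_simulator_frame(self):
        # a mitotic-only scene has truly zero-background truth; frames with
        # normal cells additionally carry un-modeled ring residuals that are
        # structure, not background
        from mitodetect.simulate import SimulationParams, simulate_frame

        params = SimulationParams(n_normal_cells=0, seed=0)
        observed, _, f_mitotic, _ = simulate_frame(params)
        res = restore(observed, params.make_psf(), sign="mitotic")
        background = f_mitotic == 0
        quiet = res.restored < 1e-3 * res.restored.max()
        assert (quiet & background).sum() / background.sum() >= 0.99

    def test_invalid_sign_rejected(self, small_psf):
        with pytest.raises(ValueError):
            restore(np.zeros((4, 4)), small_psf, sign="inverted")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RestorationConfig(w_smooth=-1.0)
        with pytest.raises(ValueError):
            RestorationConfig(tol=0.0)
        with pytest.raises(ValueError):
            RestorationConfig(reweight_eps=0.0)
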