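"""Model assembly, Gibbs fitting, variance partition, prediction."""

import numpy as np
import pytest

from hybridnorm.enviro import OmegaKernel
from hybridnorm.kernels import HybridSet, Kernel, incidence_matrix, sca_kernel
from hybridnorm.model import (
    MODEL_TERMS,
    ModelSpec,
    ModelTerm,
    SamplerConfig,
    build_terms,
    fit,
    predict_cells,
    variance_partition,
)
from hybridnorm.pipeline import PipelineConfig, prepare_kernels


@pytest.fixture(scope="module")
def built(small_bundle, small_omega):
    bundle, _ = small_bundle
    kernels, _ = prepare_kernels(bundle, PipelineConfig(n_days=20))
    return bundle, kernels, small_omega


class TestBuildTerms:
    @pytest.mark.parametrize(
        "model_id,n_terms",
        [("M1", 3), ("M2", 4), ("M3", 7), ("M4", 7), ("M5", 10)],
    )
    def test_term_counts(self, built, model_id, n_terms):
        bundle, kernels, om = built
        spec = build_terms(model_id, bundle, kernels, omega=om)
        assert len(spec.terms) == n_terms

    def test_m4_without_omega_rejected(self, built):
        bundle, kernels, _ = built
        with pytest.raises(ValueError, match="Omega"):
            build_terms("M4", bundle, kernels, omega=None)

    def test_identity_omega_makes_m4_equal_m3(self, built):
        bundle, kernels, _ = built
        envs = bundle.env_ids
        om = OmegaKernel(name="Omega", level="environment",
                        matrix=np.eye(len(envs)), ids=envs, q=1)
        m3 = build_terms("M3", bundle, kernels, omega=None, rescale=False)
        m4 = build_terms("M4", bundle, kernels, omega=om, rescale=False)
        for t3, t4 in zip(MODEL_TERMS["M3"], MODEL_TERMS["M4"]):
            np.testing.assert_allclose(
                m3.obs_kernel(t3).matrix, m4.obs_kernel(t4).matrix
            )

    def test_sca_term_matches_explicit_hybrid_kernel(self, built):
        """The factorized SCA term equals the Hadamard hybrid kernel expanded."""
        bundle, kernels, om = built
        spec = build_terms("M2", bundle, kernels, omega=None, rescale=False)
        K_factor = spec.obs_kernel("G_P1xP2").matrix
        hyb_kernel = sca_kernel(kernels["G_P1"], kernels["G_P2"], bundle.hybrids)
        Z = incidence_matrix([h for h, _ in spec.cells], hyb_kernel.ids)
        np.testing.assert_allclose(K_factor, Z @ hyb_kernel.matrix @ Z.T, atol=1e-10)

    def test_every_term_kernel_is_psd(self, built):
        bundle, kernels, om = built
        spec = build_terms("M5", bundle, kernels, omega=om)
        for name in spec.term_names:
            spec.obs_kernel(name).validate()


def _single_term_spec(K: np.ndarray, seed=0):
    n = K.shape[0]
    envs = ["E1"]
    cells = [(f"H{i}", "E1") for i in range(n)]
    hybrids = HybridSet([(f"H{i}", f"P{i}", "T") for i in range(n)])
    ker = Kernel("G", "hybrid", K, [f"P{i}" for i in range(n)])
    term = ModelTerm("G", ((ker, "parent1"),), hybrids)
    return ModelSpec("M1", cells, [term])


class TestFit:
    def test_constant_response_degenerates_cleanly(self):
        spec = _single_term_spec(np.eye(30))
        y = np.full(30, 42.0)
        res = fit(spec, y, SamplerConfig(n_iter=600, burn_in=200, seed=0))
        assert res.varcomps["residual"] < 1e-4
        assert res.mu == pytest.approx(42.0, abs=0.1)

    def test_single_kernel_fit_matches_gblup_closed_form(self):
        """Posterior-mean effects agree with the ridge/GBLUP solution at the
        posterior-mean variance ratio."""
        rng = np.random.default_rng(1)
        n = 50
        K = np.eye(n)
        g = rng.standard_normal(n) * np.sqrt(3.0)
        y = 5.0 + g + rng.standard_normal(n)
        spec = _single_term_spec(K)
        res = fit(spec, y, SamplerConfig(seed=2))
        lam = res.varcomps["residual"] / res.varcomps["G"]
        blup = K @ np.linalg.solve(K + lam * np.eye(n), y - res.mu)
        rms = np.sqrt(np.mean((res.effects["G"] - blup) ** 2))
        assert rms / np.sqrt(np.mean(blup**2)) < 0.02

    def test_two_term_variance_recovery(self):
        """Posterior means land near generating variances (3, 1, 1)."""
        rng = np.random.default_rng(3)
        n = 300
        diffs = []
        for seed in range(3):
            B = rng.normal(size=(n, 40))
            K = B @ B.T / 40
            K /= np.mean(np.diag(K))
            envs = [f"E{i % 6}" for i in range(n)]
            cells = [(f"H{i}", envs[i]) for i in range(n)]
            hybrids = HybridSet([(f"H{i}", f"P{i}", "T") for i in range(n)])
            gker = Kernel("G", "hybrid", K, [f"P{i}" for i in range(n)])
            eker = Kernel("I_E", "environment", np.eye(6),
                          [f"E{j}" for j in range(6)])
            terms = [ModelTerm("G", ((gker, "parent1"),), hybrids),
                     ModelTerm("E", ((eker, "env"),), hybrids)]
            spec = ModelSpec("M1", cells, terms)
            L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
            g = L @ rng.standard_normal(n) * np.sqrt(3.0)
            e_eff = rng.standard_normal(6)
            y = g + np.array([e_eff[i % 6] for i in range(n)]) + rng.standard_normal(n)
            res = fit(spec, y, SamplerConfig(n_iter=2000, burn_in=600, seed=seed))
            diffs.append(res.varcomps["G"])
        assert np.mean(diffs) == pytest.approx(3.0, rel=0.3)

    def test_deterministic_given_seed(self, built):
        bundle, kernels, om = built
        spec = build_terms("M1", bundle, kernels)
        cfg = SamplerConfig(n_iter=300, burn_in=100, seed=9)
        r1 = fit(spec, bundle.pheno.y, cfg)
        r2 = fit(spec, bundle.pheno.y, cfg)
        assert r1.mu == r2.mu
        np.testing.assert_array_equal(r1.fitted, r2.fitted)


class TestVariancePartition:
    def test_symmetric_single_term_splits_fifty_fifty(self):
        """With an identity kernel and equal variances the posterior is
        symmetric in (sigma2_g, sigma2_e); the split is unidentified, so the
        chain wanders a ridge — average a few chains to beat that noise."""
        spec = _single_term_spec(np.eye(200))
        rng = np.random.default_rng(4)
        y = rng.normal(size=200) * np.sqrt(2.0)
        shares = []
        for s in range(3):
            res = fit(spec, y, SamplerConfig(seed=5 + s))
            shares.append(variance_partition(res).percentages["G"])
        assert np.mean(shares) == pytest.approx(50.0, abs=12.0)

    def test_percentages_sum_to_100(self, built):
        bundle, kernels, om = built
        spec = build_terms("M5", bundle, kernels, omega=om)
        res = fit(spec, bundle.pheno.y,
                  SamplerConfig(n_iter=400, burn_in=100, seed=0))
        vp = variance_partition(res)
        assert sum(vp.percentages.values()) == pytest.approx(100.0, abs=1e-6)
        assert len(vp.percentages) == 11  # 10 random terms + residual


class TestPredictCells:
    def test_in_sample_prediction_equals_fitted(self, built):
        bundle, kernels, om = built
        spec = build_terms("M3", bundle, kernels)
        res = fit(spec, bundle.pheno.y,
                  SamplerConfig(n_iter=400, burn_in=100, seed=1))
        pred = predict_cells(res, spec.cells)
        np.testing.assert_allclose(pred, res.fitted, atol=1e-8)

    def test_unobserved_environment_under_m3_has_no_interaction(self, built):
        """For a new environment, the reaction-norm terms gated by the
        environment identity contribute exactly zero: the M3 prediction
        reduces to the across-environment genetic prediction."""
        bundle, kernels, om = built
        held_out = bundle.env_ids[-1]
        mask = bundle.pheno.df["env"] != held_out
        cells_train = [c for c, keep in zip(bundle.pheno.cells(), mask) if keep]
        y_train = bundle.pheno.y[mask.to_numpy()]
        spec3 = build_terms("M3", bundle, kernels, cells=cells_train)
        res3 = fit(spec3, y_train, SamplerConfig(n_iter=500, burn_in=150, seed=2))
        test_cells = [(h, held_out) for h in bundle.hybrids.ids[:10]]
        pred = predict_cells(res3, test_cells)
        genetic = res3.mu + sum(
            term.cov(test_cells, res3.cells) @ res3.pred_weights[term.name]
            for term in res3.terms
            if term.name in ("G_P1", "G_P2", "G_P1xP2")
        )
        np.testing.assert_allclose(pred, genetic, atol=1e-8)

    def test_unobserved_environment_m4_matches_dense_conditional_mean(self):
        """3-environment toy with a known Omega: held-out-environment
        GxW predictions equal the explicit Gaussian conditional mean."""
        rng = np.random.default_rng(7)
        envs = ["E1", "E2", "E3"]
        Om = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        omk = OmegaKernel(name="Omega", level="environment", matrix=Om,
                          ids=envs, q=3)
        n_h = 12
        hybrids = HybridSet([(f"H{i}", f"P{i}", "T") for i in range(n_h)])
        B = rng.normal(size=(n_h, 30))
        G = B @ B.T / 30
        gker = Kernel("G_P1", "parent1", G, [f"P{i}" for i in range(n_h)])
        cells_train = [(f"H{i}", e) for e in envs[:2] for i in range(n_h)]
        term = ModelTerm("G_P1xW", ((gker, "parent1"), (omk, "env")), hybrids)
        spec = ModelSpec("M4", cells_train, [term])
        y = rng.normal(size=len(cells_train))
        res = fit(spec, y, SamplerConfig(n_iter=800, burn_in=300, seed=8))
        test_cells = [(f"H{i}", "E3") for i in range(n_h)]
        pred = predict_cells(res, test_cells)
        # dense conditional mean: K_nt K_tt^+ g_hat
        K_tt = term.cov(cells_train, cells_train)
        K_nt = term.cov(test_cells, cells_train)
        expected = res.mu + K_nt @ np.linalg.pinv(K_tt) @ res.effects["G_P1xW"]
        np.testing.assert_allclose(pred, expected, atol=1e-6)

    def test_prediction_invariant_to_observation_reordering(self, built):
        bundle, kernels, om = built
        cells = bundle.pheno.cells()
        y = bundle.pheno.y
        perm = np.random.default_rng(0).permutation(len(cells))
        spec_a = build_terms("M2", bundle, kernels, cells=cells)
        spec_b = build_terms("M2", bundle, kernels,
                             cells=[cells[i] for i in perm])
        cfg = SamplerConfig(n_iter=2500, burn_in=800, seed=3)
        res_a = fit(spec_a, y, cfg)
        res_b = fit(spec_b, y[perm], cfg)
        probe = cells[:15]
        pa = predict_cells(res_a, probe)
        pb = predict_cells(res_b, probe)
        np.testing.assert_allclose(pa, pb, atol=0.05 * np.std(y))

    def test_unknown_parent_raises(self, built):
        bundle, kernels, om = built
        spec = build_terms("M1", bundle, kernels)
        res = fit(spec, bundle.pheno.y,
                  SamplerConfig(n_iter=300, burn_in=100, seed=4))
        with pytest.raises(KeyError):
            predict_cells(res, [("NOT_A_HYBRID", bundle.env_ids[0])])
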