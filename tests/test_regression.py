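import numpy as np
import pytest

from racer import (
    SyntheticConfig,
    fit_stage1,
    fit_stage2,
    generate_bundle,
    lasso_fit,
    predict_expression,
    weight_mir_activities,
)
from racer.regression import stage1_design


def _orthonormal_design(rng, n, p):
    raw = rng.standard_normal((n, p))
    raw -= raw.mean(axis=0)
    Q, _ = np.linalg.qr(raw)
    return np.sqrt(n) * Q


class TestLassoFit:
    def test_ols_limit_recovers_exact_slope(self):
        x = np.linspace(0.0, 1.0, 12)[:, None]
        fit = lasso_fit(x, 2.0 * x[:, 0], lam=0)
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_orthonormal_design_matches_soft_threshold(self):
        rng = np.random.default_rng(1)
        X = _orthonormal_design(rng, 32, 5)
        y = X @ rng.standard_normal(5) + 0.1 * rng.standard_normal(32)
        lam = 0.3
        fit = lasso_fit(X, y, lam=lam)
        ols = X.T @ (y - y.mean()) / 32
        oracle = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        assert np.abs(fit.coefficients - oracle).max() < 1e-6

    def test_zero_response_gives_zero_fit(self):
        rng = np.random.default_rng(0)
        fit = lasso_fit(rng.standard_normal((10, 3)), np.zeros(10), lam="cv", seed=0)
        assert np.all(fit.coefficients == 0.0)
        assert fit.rss == 0.0

    def test_no_predictors_gives_intercept_only(self):
        y = np.array([1.0, 3.0, 5.0])
        fit = lasso_fit(np.empty((3, 0)), y, lam="cv")
        assert fit.intercept == pytest.approx(3.0)
        assert fit.coefficients.size == 0

    def test_zero_variance_column_dropped_to_zero(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.full(20, 7.0), rng.standard_normal(20)])
        y = 3.0 * X[:, 1]
        fit = lasso_fit(X, y, lam=0)
        assert fit.coefficients[0] == 0.0
        assert fit.coefficients[1] == pytest.approx(3.0)

    def test_cv_is_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 6))
        y = X @ np.array([1.0, -2.0, 0, 0, 0.5, 0]) + rng.standard_normal(40)
        f1 = lasso_fit(X, y, lam="cv", seed=5)
        f2 = lasso_fit(X, y, lam="cv", seed=5)
        assert f1.lambda_selected == f2.lambda_selected
        assert np.array_equal(f1.coefficients, f2.coefficients)

    def test_rss_matches_fitted_values(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        fit = lasso_fit(X, y, lam=0.1)
        assert fit.rss == pytest.approx(float(((y - fit.fitted) ** 2).sum()), rel=1e-12)

    def test_nesting_at_lambda_zero(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        rss_sub = lasso_fit(X[:, :3], y, lam=0).rss
        rss_full = lasso_fit(X, y, lam=0).rss
        assert rss_full <= rss_sub + 1e-10


class TestWeighting:
    def test_row_scaled_by_its_mean(self):
        U = np.array([[1.0, 3.0], [0.0, 0.0]])
        out = weight_mir_activities(U)
        assert np.allclose(out, [[2.0, 6.0], [0.0, 0.0]])

    def test_weighting_squares_the_sign(self):
        assert np.allclose(
            weight_mir_activities(np.array([[-1.0, -3.0]])), [[2.0, 6.0]]
        )


class TestStage1:
    def test_noise_free_fit_matches_ols_oracle(self, noiseless_cohort):
        bundle, _ = noiseless_cohort
        fit = fit_stage1(bundle, lam=0)
        for s in [0, 5, 11]:
            design = stage1_design(bundle, s)
            Z = np.column_stack([np.ones(bundle.n_genes), design])
            beta, *_ = np.linalg.lstsq(Z, bundle.E[:, s], rcond=None)
            recovered = np.concatenate([fit.W[:, s], fit.U[:, s]])
            assert np.abs(recovered - beta[3:]).max() < 1e-4

    def test_noise_free_prediction_reproduces_expression(self, noiseless_cohort):
        bundle, _ = noiseless_cohort
        fit = fit_stage1(bundle, lam=0)
        pred = predict_expression(bundle, fit)
        assert np.abs(pred - bundle.E).max() < 1e-4

    def test_unexpressed_mirna_gets_zero_activity(self, small_cohort):
        bundle, _ = small_cohort
        bundle = bundle.copy()
        bundle.X[2, :] = 0.0
        fit = fit_stage1(bundle, lam="cv", seed=0)
        assert np.all(fit.U[2, :] == 0.0)

    def test_gene_permutation_leaves_fit_unchanged(self, small_cohort):
        bundle, _ = small_cohort
        fit = fit_stage1(bundle, lam=0.05)
        permuted = bundle.copy()
        rng = np.random.default_rng(0)
        perm = rng.permutation(bundle.n_genes)
        permuted.E = permuted.E[perm]
        permuted.C = permuted.C[perm]
        permuted.D = permuted.D[perm]
        permuted.B = permuted.B[:, perm]
        permuted.S = permuted.S[:, perm]
        permuted.genes = [bundle.genes[i] for i in perm]
        fit_p = fit_stage1(permuted, lam=0.05)
        assert np.allclose(fit.W, fit_p.W, atol=1e-8)
        assert np.allclose(fit.U, fit_p.U, atol=1e-8)

    def test_rss_bookkeeping_identity(self, small_cohort):
        bundle, _ = small_cohort
        fit = fit_stage1(bundle, lam="cv", seed=1)
        resid = bundle.E - predict_expression(bundle, fit)
        assert np.allclose(
            (resid**2).sum(axis=0), fit.rss_per_sample, rtol=1e-8, atol=1e-10
        )


class TestStage2:
    def test_scores_restricted_to_candidate_support(self, small_cohort):
        bundle, _ = small_cohort
        s1 = fit_stage1(bundle, lam="cv", seed=0)
        s2 = fit_stage2(bundle, s1, lam="cv", seed=0)
        assert np.all(s2.Theta_TF[bundle.B.T == 0] == 0.0)
        assert np.all(s2.Theta_miR[bundle.S.T == 0] == 0.0)

    def test_gene_without_candidates_gets_zero_rows(self, small_cohort):
        bundle, _ = small_cohort
        bundle = bundle.copy()
        g = 3
        bundle.B[:, g] = 0.0
        bundle.S[:, g] = 0.0
        s1 = fit_stage1(bundle, lam="cv", seed=0)
        s2 = fit_stage2(bundle, s1, lam="cv", seed=0)
        assert np.all(s2.Theta_TF[g] == 0.0) and np.all(s2.Theta_miR[g] == 0.0)

    def test_planted_edge_has_largest_mirna_score(self):
        config = SyntheticConfig(
            G=150, M=6, T=3, N=30, edge_density=0.15, noise_sd=0.05,
            effect_fraction=0.6, seed=3,
        )
        bundle, truth = generate_bundle(config)
        s1 = fit_stage1(bundle, lam="cv", seed=3)
        s2 = fit_stage2(bundle, s1, lam="cv", seed=3)
        hits = total = 0
        true_mags, null_mags = [], []
        mir_edges = truth.mir_edges()
        for m, g in mir_edges:
            gi = bundle.genes.index(g)
            mi = bundle.mirnas.index(m)
            candidates = np.flatnonzero(bundle.S[:, gi] > 0)
            for c in candidates:
                mag = abs(s2.Theta_miR[gi, c])
                (true_mags if (bundle.mirnas[c], g) in mir_edges else null_mags).append(mag)
            if candidates.size < 2:
                continue
            total += 1
            best = candidates[np.argmax(np.abs(s2.Theta_miR[gi, candidates]))]
            hits += best == mi
        # planted edges usually dominate their gene's candidate set, and
        # their scores clearly separate from non-functional candidates
        assert total > 0 and hits / total > 0.6
        assert np.mean(true_mags) > 3 * np.mean(null_mags)

    def test_rss_bookkeeping_identity(self, small_cohort):
        bundle, _ = small_cohort
        s1 = fit_stage1(bundle, lam="cv", seed=2)
        s2 = fit_stage2(bundle, s1, lam="cv", seed=2)
        resid = bundle.E - predict_expression(bundle, s2)
        assert np.allclose((resid**2).sum(axis=1), s2.rss_per_gene, rtol=1e-8, atol=1e-10)
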