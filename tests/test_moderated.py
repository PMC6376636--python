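import math
import subprocess

import numpy as np
import pytest
from scipy import stats

from rhythmdiff import (DesignError, DomainError, ExpressionMatrix, GeneFits,
                        ModelSpec, PriorEstimate, TimeBasis, build_design,
                        estimate_prior, fit_linear_models, moderated_F, moderated_t)
from rhythmdiff.moderated import trigamma_inverse


def _fits_from_arrays(X, Y):
    """Fit raw arrays through the public surface."""
    n = X.shape[0]
    ids = [f"s{i}" for i in range(n)]
    expr = ExpressionMatrix([f"g{i}" for i in range(Y.shape[0])], ids, Y)
    from rhythmdiff.design import DesignMatrix

    design = DesignMatrix(X, [f"c{j}" for j in range(X.shape[1])], ids, [], [], [])
    return fit_linear_models(expr, design)


class TestFitLinearModels:
    def test_noiseless_sinusoid_has_zero_residual_variance(self, two_condition_meta):
        t = two_condition_meta.time
        y = 0.3 + 1.7 * np.cos(2 * np.pi * (t - 5.0) / 24.0)
        expr = ExpressionMatrix(["g"], two_condition_meta.sample_ids, y[None, :])
        design = build_design(two_condition_meta, ModelSpec(TimeBasis()))
        fit = fit_linear_models(expr, design)
        assert fit.sigma2[0] == pytest.approx(0.0, abs=1e-24)
        recon = design.matrix @ fit.coefficients[0]
        np.testing.assert_allclose(recon, y, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            X = np.column_stack([np.ones(6), rng.normal(size=(6, 2))])
            Y = rng.normal(size=(3, 6))
            fit = _fits_from_arrays(X, Y)
            beta = np.linalg.solve(X.T @ X, X.T @ Y.T).T
            np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
            rss = ((Y - beta @ X.T) ** 2).sum(axis=1)
            np.testing.assert_allclose(fit.sigma2, rss / 3, atol=1e-10)
            np.testing.assert_allclose(fit.cov_unscaled, np.linalg.inv(X.T @ X),
                                       atol=1e-10)

    def test_intercept_only_gives_mean_and_variance(self, rng):
        Y = rng.normal(size=(4, 10))
        fit = _fits_from_arrays(np.ones((10, 1)), Y)
        np.testing.assert_allclose(fit.coefficients[:, 0], Y.mean(axis=1), atol=1e-12)
        np.testing.assert_allclose(fit.sigma2, Y.var(axis=1, ddof=1), atol=1e-12)

    def test_saturated_model_rejected(self, rng):
        X = np.column_stack([np.ones(3), rng.normal(size=(3, 2))])
        with pytest.raises(DesignError, match="residual degrees of freedom"):
            _fits_from_arrays(X, rng.normal(size=(2, 3)))

    def test_misaligned_samples_rejected(self, tiny_expr, two_condition_meta):
        design = build_design(two_condition_meta, ModelSpec(TimeBasis()))
        design.sample_ids = list(reversed(design.sample_ids))
        from rhythmdiff import IdentityError

        with pytest.raises(IdentityError):
            fit_linear_models(tiny_expr, design)


def _synthetic_fits(s2, dg, amean=None):
    G = len(s2)
    return GeneFits([f"g{i}" for i in range(G)], np.zeros((G, 1)), np.asarray(s2, float),
                    float(dg), np.eye(1), np.zeros(G) if amean is None else amean, None)


class TestEstimatePrior:
    def test_identical_variances_give_infinite_prior_df(self):
        prior = estimate_prior(_synthetic_fits([2.5] * 20, dg=6))
        assert math.isinf(prior.d0)
        assert float(prior.s20) == pytest.approx(2.5)

    def test_recovers_simulated_prior_parameters(self):
        # s_g^2 ~ s0^2 * F(dg, d0): true variances from a scaled inverse
        # chi-square with d0=4, s0^2=1; observed via chi-square on dg=10
        rng = np.random.default_rng(11)
        G, d0, s02, dg = 10_000, 4.0, 1.0, 10
        true_var = s02 * d0 / rng.chisquare(d0, G)
        s2 = true_var * rng.chisquare(dg, G) / dg
        prior = estimate_prior(_synthetic_fits(s2, dg))
        assert prior.d0 == pytest.approx(d0, rel=0.10)
        assert float(prior.s20) == pytest.approx(s02, rel=0.05)

    def test_two_wildly_different_variances_give_small_finite_df(self):
        prior = estimate_prior(_synthetic_fits([1e-4, 1e4], dg=10))
        assert math.isfinite(prior.d0)
        assert prior.d0 < 1.0

    def test_zero_variances_floored_and_flagged(self):
        prior = estimate_prior(_synthetic_fits([0.0, 1.0, 2.0, 1.5], dg=5))
        assert prior.zero_variance_genes.tolist() == [True, False, False, False]

    def test_all_zero_variances_rejected(self):
        with pytest.raises(DomainError, match="degenerate"):
            estimate_prior(_synthetic_fits([0.0, 0.0], dg=5))

    def test_trend_tracks_mean_dependent_variance(self):
        rng = np.random.default_rng(3)
        G, dg = 4000, 10
        amean = rng.uniform(0, 10, G)
        true_var = np.exp(0.3 * amean - 2.0)
        s2 = true_var * rng.chisquare(dg, G) / dg
        prior = estimate_prior(_synthetic_fits(s2, dg, amean), trend=True)
        s20 = prior.s20_for(G)
        # the trended prior variance must increase with average expression
        lo = s20[amean < 3].mean()
        hi = s20[amean > 7].mean()
        assert hi > 3 * lo

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for y in (0.01, 0.5, 2.0, 50.0):
            x = float(polygamma(1, y))
            assert trigamma_inverse(x) == pytest.approx(y, rel=1e-7)


class TestModeratedTests:
    def _instance(self, rng, G=40, n=10, p=4):
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        Y = rng.normal(size=(G, n))
        return X, Y, _fits_from_arrays(X, Y)

    def test_classical_limit_matches_partial_f_oracle(self, rng):
        """With d0=0 the moderated F must equal the classical partial F from
        the RSS-difference formulation."""
        X, Y, fit = self._instance(rng)
        tested = [2, 3]
        res = moderated_F(fit, PriorEstimate(0.0, 1.0), tested)
        Xr = X[:, [0, 1]]
        beta_f = np.linalg.solve(X.T @ X, X.T @ Y.T).T
        beta_r = np.linalg.solve(Xr.T @ Xr, Xr.T @ Y.T).T
        rss_f = ((Y - beta_f @ X.T) ** 2).sum(axis=1)
        rss_r = ((Y - beta_r @ Xr.T) ** 2).sum(axis=1)
        df = X.shape[0] - X.shape[1]
        F_oracle = ((rss_r - rss_f) / 2) / (rss_f / df)
        p_oracle = stats.f.sf(F_oracle, 2, df)
        np.testing.assert_allclose(res.statistic, F_oracle, atol=1e-10)
        np.testing.assert_allclose(res.p_value, p_oracle, atol=1e-12)

    def test_classical_limit_matches_ols_t_oracle(self, rng):
        import statsmodels.api as sm

        X, Y, fit = self._instance(rng, G=5)
        res = moderated_t(fit, PriorEstimate(0.0, 1.0), 1)
        for g in range(5):
            ols = sm.OLS(Y[g], X).fit()
            assert res.statistic[g] == pytest.approx(ols.tvalues[1], abs=1e-12)
            assert res.p_value[g] == pytest.approx(ols.pvalues[1], abs=1e-12)

    def test_zero_coefficients_give_null_statistic(self, rng):
        X = np.column_stack([np.ones(8), np.tile([0.0, 1.0], 4)])
        fit = _fits_from_arrays(X, rng.normal(size=(2, 8)))
        fit.coefficients[:, 1] = 0.0
        res_f = moderated_F(fit, PriorEstimate(4.0, 1.0), [1])
        res_t = moderated_t(fit, PriorEstimate(4.0, 1.0), 1)
        np.testing.assert_array_equal(res_f.statistic, 0.0)
        np.testing.assert_array_equal(res_f.p_value, 1.0)
        np.testing.assert_array_equal(res_t.statistic, 0.0)
        np.testing.assert_array_equal(res_t.p_value, 1.0)

    def test_single_coefficient_f_is_squared_t(self, rng):
        X, Y, fit = self._instance(rng)
        prior = estimate_prior(fit)
        f = moderated_F(fit, prior, [2])
        t = moderated_t(fit, prior, 2)
        np.testing.assert_allclose(f.statistic, t.statistic**2, atol=1e-10)
        np.testing.assert_allclose(f.p_value, t.p_value, atol=1e-12)

    def test_doubling_noise_halves_t_at_classical_limit(self, rng):
        X = np.column_stack([np.ones(12), rng.normal(size=(12, 1))])
        beta = np.array([[1.0, 0.8]])
        resid = rng.normal(size=(1, 12))
        resid -= resid @ X @ np.linalg.solve(X.T @ X, X.T)  # orthogonal to design
        y1 = beta @ X.T + resid
        y2 = beta @ X.T + 2 * resid
        t1 = moderated_t(_fits_from_arrays(X, y1), PriorEstimate(0.0, 1.0), 1)
        t2 = moderated_t(_fits_from_arrays(X, y2), PriorEstimate(0.0, 1.0), 1)
        assert abs(t2.statistic[0]) == pytest.approx(abs(t1.statistic[0]) / 2, rel=1e-10)

    def test_shrinkage_bound_holds_per_gene(self, rng):
        X, Y, fit = self._instance(rng, G=200)
        prior = estimate_prior(fit)
        res = moderated_F(fit, prior, [1, 2])
        s20 = prior.s20_for(fit.n_genes)
        lo = np.minimum(fit.sigma2, s20)
        hi = np.maximum(fit.sigma2, s20)
        assert np.all(res.posterior_var >= lo - 1e-12)
        assert np.all(res.posterior_var <= hi + 1e-12)

    def test_infinite_prior_df_uses_prior_variance_exactly(self, rng):
        X, Y, fit = self._instance(rng)
        res = moderated_F(fit, PriorEstimate(math.inf, 0.7), [1, 2])
        np.testing.assert_allclose(res.posterior_var, 0.7)
        # chi-square reference: p = P(chi2_k > k F)
        np.testing.assert_allclose(res.p_value,
                                   stats.chi2.sf(2 * res.statistic, 2), atol=1e-12)

    def test_f_increases_along_fixed_coefficient_direction(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=(10, 2))])
        resid = rng.normal(size=10)
        resid -= X @ np.linalg.solve(X.T @ X, X.T @ resid)
        direction = X[:, 1] - X[:, 2]
        Y = np.stack([c * direction + resid for c in (0.0, 0.5, 1.0, 2.0)])
        fit = _fits_from_arrays(X, Y)
        res = moderated_F(fit, PriorEstimate(math.inf, 1.0), [1, 2])
        assert np.all(np.diff(res.statistic) > 0)

    def test_empty_tested_set_rejected(self, rng):
        X, Y, fit = self._instance(rng, G=2)
        with pytest.raises(DesignError):
            moderated_F(fit, PriorEstimate(0.0, 1.0), [])

    def test_null_pvalues_roughly_uniform_under_moderation(self, rng):
        X = np.column_stack([np.ones(12), rng.normal(size=(12, 2))])
        Y = rng.normal(size=(2000, 12))
        fit = _fits_from_arrays(X, Y)
        prior = estimate_prior(fit)
        res = moderated_F(fit, prior, [1, 2])
        assert stats.kstest(res.p_value, "uniform").statistic < 0.05


class TestAgainstLimma:
    def test_untrended_moderation_matches_limma(self, tmp_path, rng):
        """Independent cross-check: the R limma package, fed the same matrix
        and design, must reproduce the prior, moderated F and t results."""
        n, G = 12, 150
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float),
                             np.cos(np.linspace(0, 4, n)), np.sin(np.linspace(0, 4, n))])
        sd = np.exp(rng.normal(0, 0.5, G))
        Y = rng.normal(size=(G, n)) * sd[:, None]
        fit = _fits_from_arrays(X, Y)
        prior = estimate_prior(fit, trend=False)
        res_f = moderated_F(fit, prior, [2, 3])
        res_t = moderated_t(fit, prior, 1)
        np.savetxt(tmp_path / "y.txt", Y)
        np.savetxt(tmp_path / "x.txt", X)
        script = """
        suppressMessages(library(limma))
        args <- commandArgs(trailingOnly=TRUE)
        y <- as.matrix(read.table(args[1])); X <- as.matrix(read.table(args[2]))
        fit <- eBayes(lmFit(y, X), trend=FALSE)
        cf <- classifyTestsF(fit[, 3:4], fstat.only=TRUE)
        pF <- pf(as.numeric(cf), attr(cf,'df1'), attr(cf,'df2'), lower.tail=FALSE)
        out <- cbind(rep(fit$df.prior, nrow(y)), rep(fit$s2.prior, nrow(y)),
                     as.numeric(cf), pF, fit$t[,2], fit$p.value[,2])
        write.table(format(out, digits=17), args[3], row.names=FALSE, col.names=FALSE,
                    quote=FALSE)
        """
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "oracle.R"), str(tmp_path / "y.txt"),
                        str(tmp_path / "x.txt"), str(tmp_path / "out.txt")],
                       check=True, capture_output=True)
        ref = np.loadtxt(tmp_path / "out.txt")
        assert prior.d0 == pytest.approx(ref[0, 0], rel=1e-6)
        assert float(prior.s20) == pytest.approx(ref[0, 1], rel=1e-9)
        np.testing.assert_allclose(res_f.statistic, ref[:, 2], rtol=1e-9)
        np.testing.assert_allclose(res_f.p_value, ref[:, 3], atol=1e-12)
        np.testing.assert_allclose(res_t.statistic, ref[:, 4], rtol=1e-9)
        np.testing.assert_allclose(res_t.p_value, ref[:, 5], atol=1e-12)
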