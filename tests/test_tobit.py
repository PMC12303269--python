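"""Tobit likelihood and fitting: closed forms, oracles, and recovery."""

import numpy as np
import pytest
from scipy import integrate, stats

from drainspec.tobit import (
    backward_select,
    fit_tobit,
    mean_squared_error,
    regression_metrics,
    tobit_loglik,
    tobit_mixed_loglik,
)


class TestLoglikClosedForms:
    def test_reduces_to_gaussian_when_uncensored(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        beta = np.array([1.0, 2.0])
        y = X @ beta + rng.normal(size=30)
        ll = tobit_loglik(beta, 1.3, X, y, censor_bound=y.min() - 1.0)
        gaussian = stats.norm.logpdf(y, loc=X @ beta, scale=1.3).sum()
        assert ll == pytest.approx(gaussian, abs=1e-10)

    def test_single_censored_observation_at_zero(self):
        """One observation censored at L=0 with x'beta = 0, sigma = 1
        contributes log Phi(0) = log 0.5."""
        X = np.array([[1.0]])
        ll = tobit_loglik(np.array([0.0]), 1.0, X, np.array([0.0]), censor_bound=0.0)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            tobit_loglik([0.0], 0.0, np.ones((2, 1)), np.array([1.0, 2.0]))

    def test_responses_below_bound_impossible(self):
        with pytest.raises(ValueError):
            tobit_loglik([0.0], 1.0, np.ones((2, 1)), np.array([-1.0, 2.0]), 0.0)


class TestMixedLoglikOracle:
    def test_matches_numerically_integrated_likelihood(self):
        """Gauss-Hermite marginal likelihood vs direct quadrature over the
        random intercept on a tiny instance (2 groups x 3 observations)."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 1))
        beta = np.array([0.5, 1.2])  # intercept, slope
        sigma, tau, L = 0.8, 0.7, 0.0
        y = np.maximum(beta[0] + X[:, 0] * beta[1] + rng.normal(0, 1, 6), 0.0)
        groups = np.array([0, 0, 0, 1, 1, 1])

        def group_lik(idx):
            Xg, yg = X[idx], y[idx]

            def integrand(b):
                Xd = np.column_stack([np.ones(len(yg)), Xg])
                mu = Xd @ beta + b
                terms = np.where(
                    yg > L,
                    stats.norm.pdf(yg, mu, sigma),
                    stats.norm.cdf((L - mu) / sigma),
                )
                return np.prod(terms) * stats.norm.pdf(b, 0, tau)

            val, _ = integrate.quad(integrand, -8 * tau, 8 * tau, limit=200)
            return np.log(val)

        oracle = group_lik(np.arange(3)) + group_lik(np.arange(3, 6))
        gh = tobit_mixed_loglik(beta, sigma, tau, X, y, groups, censor_bound=L)
        assert gh == pytest.approx(oracle, abs=1e-6)


class TestFitting:
    def test_equals_ols_when_censoring_inactive(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 5.0 + 2.0 * x + rng.normal(size=200)
        fit = fit_tobit(x, y, censor_bound=y.min() - 10.0)
        Xd = np.column_stack([np.ones(200), x])
        ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-5)

    def test_parameter_recovery_left_censored(self):
        """y* = 2 + 3x + N(0,1) censored at 0, n = 500: MLE within +/-0.15."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = np.maximum(2.0 + 3.0 * x + rng.normal(size=500), 0.0)
        fit = fit_tobit(x, y, censor_bound=0.0)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(2.0, abs=0.15)
        assert fit.beta[1] == pytest.approx(3.0, abs=0.15)
        assert fit.sigma == pytest.approx(1.0, abs=0.15)

    def test_recovery_bias_small_over_replicates(self):
        """Median absolute bias of each coefficient < 10% of its magnitude
        over 50 seeded replicates of the censored design."""
        biases = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=400)
            y = np.maximum(1.5 + 2.0 * x + rng.normal(size=400), 0.0)
            fit = fit_tobit(x, y, compute_se=False)
            biases.append([fit.beta[0] - 1.5, fit.beta[1] - 2.0])
        med = np.median(np.abs(np.array(biases)), axis=0)
        assert med[0] < 0.15 and med[1] < 0.20

    def test_tau_boundary_when_no_group_effect(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=400)
        groups = np.repeat(np.arange(80), 5)
        y = np.maximum(1.0 + 2.0 * x + rng.normal(size=400), 0.0)
        fit_re = fit_tobit(x, y, random_intercept=True, groups=groups)
        fit_fe = fit_tobit(x, y)
        # with no true group effect the variance estimate sits near the
        # boundary and the fixed effects match the plain Tobit fit
        assert fit_re.tau**2 < 0.05
        np.testing.assert_allclose(fit_re.beta, fit_fe.beta, atol=0.01)

    def test_recovers_random_intercept_sd(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=600)
        groups = np.repeat(np.arange(120), 5)
        b = rng.normal(0, 1.0, 120)[groups]
        y = np.maximum(1.0 + 2.0 * x + b + rng.normal(size=600), 0.0)
        fit = fit_tobit(x, y, random_intercept=True, groups=groups)
        assert fit.tau == pytest.approx(1.0, abs=0.25)
        assert fit.beta[1] == pytest.approx(2.0, abs=0.15)

    def test_random_intercept_improves_out_of_fold_mse(self):
        """With a real patient effect, the mixed model's out-of-fold MSE does
        not exceed the fixed-effects model's (paired, fixed seed)."""
        rng = np.random.default_rng(9)
        n_groups = 60
        sizes = rng.integers(2, 6, n_groups)
        groups = np.repeat(np.arange(n_groups), sizes)
        n = groups.size
        x = rng.normal(size=n)
        b = rng.normal(0, 1.2, n_groups)[groups]
        y = np.maximum(1.0 + 1.5 * x + b + rng.normal(0, 0.7, n), 0.0)
        from drainspec.validation import make_folds

        folds = make_folds(np.arange(n), 5, seed=1)
        mse = {}
        for re_flag in (False, True):
            errs = []
            for f in range(5):
                tr, te = folds != f, folds == f
                fit = fit_tobit(
                    x[tr], y[tr], random_intercept=re_flag,
                    groups=groups[tr] if re_flag else None, compute_se=False,
                )
                errs.append(mean_squared_error(fit.predict(x[te][:, None]), y[te]))
            mse[re_flag] = np.mean(errs)
        assert mse[True] <= mse[False] + 1e-6

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            fit_tobit(np.arange(5.0), np.zeros(5), censor_bound=0.0)

    def test_raising_bound_never_shrinks_censored_count(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        y = np.maximum(1.0 + x + rng.normal(size=200), 0.0)
        counts = []
        for bound in (-1.0, 0.0):
            yb = np.maximum(y, bound)
            counts.append(fit_tobit(x, yb, censor_bound=bound, compute_se=False).n_censored)
        assert counts[0] <= counts[1]


class TestBackwardSelection:
    def test_noise_covariate_removed_in_most_replicates(self):
        """A pure-noise covariate is dropped in >= 90% of seeded replicates."""
        removed_count = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 500
            x_signal = rng.normal(size=n)
            x_noise = rng.normal(size=n)
            y = np.maximum(1.0 + 2.0 * x_signal + rng.normal(size=n), 0.0)
            X = np.column_stack([x_signal, x_noise])
            fit, removed = backward_select(X, y, ["signal", "noise"])
            if "noise" in removed:
                removed_count += 1
            assert "signal" in fit.feature_names
        assert removed_count >= 0.9 * reps

    def test_strong_covariates_all_retained(self):
        rng = np.random.default_rng(5)
        n = 500
        X = rng.normal(size=(n, 3))
        y = np.maximum(1.0 + X @ np.array([2.0, -1.5, 1.0]) + rng.normal(size=n), 0.0)
        fit, removed = backward_select(X, y, ["a", "b", "c"])
        assert removed == []
        assert fit.feature_names == ["a", "b", "c"]

    def test_intercept_only_model_allowed_and_intercept_kept(self):
        rng = np.random.default_rng(6)
        n = 300
        X = rng.normal(size=(n, 2))
        y = np.maximum(1.0 + rng.normal(size=n), 0.0)  # no covariate effect
        fit, removed = backward_select(X, y, ["u", "v"])
        assert set(removed) <= {"u", "v"}
        assert fit.beta.size == len(fit.feature_names) + 1  # intercept survives


class TestRegressionMetrics:
    def test_zero_fold_diffs_corrected_equals_global(self):
        m = regression_metrics(2.5, np.zeros(5), variance=10.0)
        assert m.mse_global_corrected == 2.5
        assert m.r2 == pytest.approx(1 - 2.5 / 10.0)

    def test_perfect_predictions(self):
        truth = np.array([1.0, 2.0, 3.0])
        assert mean_squared_error(truth, truth) == 0.0
        m = regression_metrics(0.0, np.zeros(5), variance=1.0)
        assert m.r2 == 1.0

    def test_variance_must_be_positive(self):
        with pytest.raises(ValueError):
            regression_metrics(1.0, np.zeros(5), variance=0.0)
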