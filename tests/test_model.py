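"""Spatial regression core: correlation, GLS, likelihoods, stepwise OLS."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import multivariate_normal

from streamtn.exceptions import FittingError, ValidationError
from streamtn.model import (
    SpatialGLS,
    StepwiseLinearRegression,
    correlation_matrix,
    exponential_correlation,
    fit_spatial,
    gls_beta,
    gls_sigma2,
    log_likelihood,
    profile_log_likelihood,
    profile_surface,
    stepwise_ols,
)


def random_instance(rng, n=10, p=3, theta1=0.2, theta2=40.0):
    """Random design, coordinates, distances and correlated response."""
    xy = rng.uniform(0, 100, size=(n, 2))
    D = squareform(pdist(xy))
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    omega = correlation_matrix(D, theta1, theta2)
    beta = rng.normal(size=p)
    y = X @ beta + np.linalg.cholesky(omega) @ rng.normal(size=n)
    return X, y, D, omega


class TestCorrelation:
    def test_piecewise_values(self):
        assert exponential_correlation(0.0, 0.3, 50.0) == 1.0
        assert exponential_correlation(10.0, 1.0, 50.0) == 0.0  # pure nugget
        assert exponential_correlation(50.0, 0.0, 50.0) == pytest.approx(np.exp(-1), abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            exponential_correlation(-1.0, 0.1, 50.0)
        with pytest.raises(ValidationError):
            exponential_correlation(1.0, 1.2, 50.0)
        with pytest.raises(ValidationError):
            exponential_correlation(1.0, 0.1, -5.0)

    def test_matrix_nugget_identity(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert np.allclose(correlation_matrix(D, 1.0, 50.0), np.eye(2))

    def test_matrix_two_sites_at_range(self):
        D = np.array([[0.0, 50.0], [50.0, 0.0]])
        omega = correlation_matrix(D, 0.0, 50.0)
        assert omega[0, 1] == pytest.approx(np.exp(-1))
        assert np.all(np.diag(omega) == 1.0)

    def test_psd_contract(self):
        rng = np.random.default_rng(3)
        D = squareform(pdist(rng.uniform(0, 100, size=(15, 2))))
        omega = correlation_matrix(D, 0.05, 80.0)
        assert np.linalg.eigvalsh(omega).min() > -1e-10


class TestGLS:
    def test_identity_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(8), rng.normal(size=(8, 2))])
        y = rng.normal(size=8)
        beta = gls_beta(X, y, np.eye(8))
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(beta, ols, atol=1e-10)
        sigma2 = gls_sigma2(X, y, np.eye(8), beta)
        assert sigma2 == pytest.approx(np.mean((y - X @ beta) ** 2))

    def test_intercept_only_mean(self):
        X = np.ones((3, 1))
        assert gls_beta(X, np.array([1.0, 2.0, 3.0]), np.eye(3))[0] == pytest.approx(2.0)

    def test_perfect_fit_zero_variance(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        beta = np.array([1.0, 2.0])
        assert gls_sigma2(X, X @ beta, np.eye(4), beta) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_explicit_inverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        X, y, D, omega = random_instance(rng, n=n)
        oi = np.linalg.inv(omega)
        beta_oracle = np.linalg.inv(X.T @ oi @ X) @ X.T @ oi @ y
        beta = gls_beta(X, y, omega)
        assert np.allclose(beta, beta_oracle, atol=1e-9)
        r = y - X @ beta_oracle
        assert gls_sigma2(X, y, omega, beta) == pytest.approx(r @ oi @ r / n, abs=1e-9)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(FittingError, match="collinear"):
            gls_beta(X, np.zeros(6), np.eye(6), names=["intercept", "a", "b"])


class TestLikelihood:
    def test_matches_scipy_multivariate_normal(self):
        rng = np.random.default_rng(5)
        X, y, D, omega = random_instance(rng, n=7)
        beta = rng.normal(size=X.shape[1])
        sigma2 = 0.8
        ours = log_likelihood(0.2, 40.0, beta, sigma2, X, y, D)
        ref = multivariate_normal(mean=X @ beta, cov=sigma2 * omega).logpdf(y)
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_independence_limit_is_iid_gaussian(self):
        rng = np.random.default_rng(6)
        X, y, D, _ = random_instance(rng, n=9)
        beta = gls_beta(X, y, np.eye(9))
        sigma2 = gls_sigma2(X, y, np.eye(9), beta)
        ours = log_likelihood(1.0, 40.0, beta, sigma2, X, y, D)
        from scipy.stats import norm

        iid = norm(loc=X @ beta, scale=np.sqrt(sigma2)).logpdf(y).sum()
        assert ours == pytest.approx(iid, abs=1e-8)

    def test_plugin_estimators_maximize(self):
        rng = np.random.default_rng(7)
        X, y, D, omega = random_instance(rng, n=10)
        beta = gls_beta(X, y, omega)
        sigma2 = gls_sigma2(X, y, omega, beta)
        at_max = log_likelihood(0.2, 40.0, beta, sigma2, X, y, D)
        for delta in (0.05, -0.08):
            perturbed = log_likelihood(0.2, 40.0, beta + delta, sigma2, X, y, D)
            assert at_max >= perturbed

    def test_bivariate_closed_form(self):
        # n=2: the bivariate normal density log can be written out by hand
        D = np.array([[0.0, 30.0], [30.0, 0.0]])
        X = np.ones((2, 1))
        y = np.array([1.0, -0.5])
        beta = np.array([0.2])
        sigma2, rho_t1, rho_t2 = 0.7, 0.1, 60.0
        rho = (1 - rho_t1) * np.exp(-30.0 / rho_t2)
        r = y - X @ beta
        quad = (r[0] ** 2 - 2 * rho * r[0] * r[1] + r[1] ** 2) / (1 - rho**2)
        hand = -np.log(2 * np.pi) - 0.5 * np.log(sigma2**2 * (1 - rho**2)) - quad / (2 * sigma2)
        ours = log_likelihood(rho_t1, rho_t2, beta, sigma2, X, y, D)
        assert ours == pytest.approx(hand, abs=1e-10)

    def test_sigma2_must_be_positive(self):
        X, y, D, _ = random_instance(np.random.default_rng(1), n=5)
        with pytest.raises(ValidationError):
            log_likelihood(0.1, 10.0, np.zeros(3), 0.0, X, y, D)


class TestProfileLikelihood:
    @pytest.mark.parametrize("seed", range(5))
    def test_equals_full_likelihood_at_plugins(self, seed):
        rng = np.random.default_rng(seed)
        X, y, D, _ = random_instance(rng, n=12)
        t1, t2 = float(rng.uniform(0, 1)), float(rng.uniform(5, 200))
        omega = correlation_matrix(D, t1, t2)
        beta = gls_beta(X, y, omega)
        sigma2 = gls_sigma2(X, y, omega, beta)
        assert profile_log_likelihood(t1, t2, X, y, D) == pytest.approx(
            log_likelihood(t1, t2, beta, sigma2, X, y, D), abs=1e-8
        )

    def test_surface_consistent_with_fit(self):
        rng = np.random.default_rng(11)
        X, y, D, _ = random_instance(rng, n=12)
        fit = SpatialGLS(grid_size=12).fit(X, y, D=D)
        surf = profile_surface(X, y, D, [fit.theta1_], [fit.theta2_])
        assert len(surf) == 1
        assert surf["profile_loglik"].iloc[0] == pytest.approx(fit.log_likelihood_, abs=1e-8)

    def test_pure_nugget_row_constant_in_theta2(self):
        rng = np.random.default_rng(12)
        X, y, D, _ = random_instance(rng, n=10)
        surf = profile_surface(X, y, D, [1.0], [5.0, 50.0, 500.0])
        assert surf["profile_loglik"].nunique() == 1  # theta2 unidentifiable

    def test_empty_grid_rejected(self):
        X, y, D, _ = random_instance(np.random.default_rng(0), n=5)
        with pytest.raises(ValidationError):
            profile_surface(X, y, D, [], [1.0])


class TestSpatialGLSFit:
    def test_noiseless_recovery_is_exact(self):
        rng = np.random.default_rng(21)
        xy = rng.uniform(0, 100, size=(12, 2))
        D = squareform(pdist(xy))
        X = np.column_stack([np.ones(12), rng.normal(size=(12, 2))])
        beta = np.array([1.5, -0.7, 0.3])
        fit = fit_spatial(X, X @ beta, D)
        assert np.allclose(fit.beta_, beta, atol=1e-8)

    def test_nugget_limit_reproduces_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(22)
        X, y, D, _ = random_instance(rng, n=15)
        fit = SpatialGLS(theta1=1.0, theta2=50.0).fit(X, y, D=D)
        ref = sm.OLS(y, X).fit().params
        assert np.allclose(fit.beta_, ref, atol=1e-10)

    def test_box_constraints_respected(self):
        rng = np.random.default_rng(23)
        X, y, D, _ = random_instance(rng, n=14)
        fit = SpatialGLS(grid_size=8).fit(X, y, D=D)
        assert 0.0 <= fit.theta1_ <= 1.0
        lo, hi = 1.0, 4.0 * D.max()
        assert lo <= fit.theta2_ <= hi

    def test_refined_never_below_grid_best(self):
        rng = np.random.default_rng(24)
        X, y, D, _ = random_instance(rng, n=14)
        fit = SpatialGLS(grid_size=8).fit(X, y, D=D)
        assert fit.log_likelihood_ >= fit.grid_best_[2] - 1e-12

    def test_requires_distance_matrix(self):
        with pytest.raises(ValidationError, match="distance"):
            SpatialGLS().fit(np.ones((5, 1)), np.zeros(5))

    def test_sklearn_params_roundtrip(self):
        est = SpatialGLS(grid_size=10, n_neighbors=4)
        assert SpatialGLS(**est.get_params()).get_params() == est.get_params()


class TestStepwise:
    def test_strong_effect_selected(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=60)
        y = 2.0 * x + rng.normal(scale=0.5, size=60)
        fit = StepwiseLinearRegression().fit(x[:, None], y, feature_names=["signal"])
        assert fit.selected_ == ["signal"]
        assert fit.coef_[0] > 0

    def test_noise_rejected_and_empty_model_ok(self):
        rng = np.random.default_rng(32)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40) * 5 + 1.0
        fit = StepwiseLinearRegression(alpha=1e-6).fit(X, y)
        assert fit.selected_ == []
        assert np.allclose(fit.predict(X), fit.intercept_)

    def test_type_one_error_rate_single_candidate(self):
        """With one pure-noise candidate the selection rate matches alpha."""
        rng = np.random.default_rng(33)
        hits = 0
        reps = 400
        for _ in range(reps):
            X = rng.normal(size=(25, 1))
            y = rng.normal(size=25)
            if StepwiseLinearRegression(alpha=0.05).fit(X, y).selected_:
                hits += 1
        assert 0.02 <= hits / reps <= 0.08  # 5% within Monte-Carlo error

    def test_diagnostics_reported(self):
        rng = np.random.default_rng(34)
        X = rng.normal(size=(50, 2))
        y = X @ np.array([1.0, -1.0]) + rng.normal(scale=0.3, size=50)
        fit = stepwise_ols(
            __import__("pandas").DataFrame(X, columns=["a", "b"]), y
        )
        assert set(fit.selected_) == {"a", "b"}
        assert set(fit.vif_) == {"a", "b"}
        assert 0.0 <= fit.het_pvalue_ <= 1.0
        assert fit.diagnostics_ok_["vif_below_10"]
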