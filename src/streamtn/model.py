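"""Spatial regression of LnTN by profile maximum likelihood.

Model
-----
``Y = X beta + eps`` with ``eps ~ N(0, sigma^2 Omega(d; theta1, theta2))`` and
an exponential auto-correlation function

    C(d) = 1                          for d = 0
    C(d) = (1 - theta1) exp(-d/theta2) for d > 0

where ``theta1`` in [0, 1] is the nugget proportion and ``theta2`` > 0 the
range in km.  For fixed ``(theta1, theta2)`` the likelihood maximizers are the
GLS estimator ``beta_hat = (X' Omega^-1 X)^-1 X' Omega^-1 Y`` and
``sigma2_hat = (Y - X beta_hat)' Omega^-1 (Y - X beta_hat) / n`` (ML divisor
``n``, not ``n - p``).  Plugging both back in gives the profile log-likelihood

    l_p(theta1, theta2) = -(n/2) log(2 pi) - (n/2) log(sigma2_hat)
                          - (1/2) log|Omega| - n/2

which is maximized over a coarse grid followed by bounded local refinement.
All ``Omega^-1`` applications go through Cholesky solves; no explicit inverse
is ever formed.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import FittingError, ValidationError

_LOG2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------
# correlation structure
# --------------------------------------------------------------------------

def exponential_correlation(d, theta1: float, theta2: float):
    """Exponential correlation with nugget proportion: 1 at d=0, else
    ``(1-theta1) exp(-d/theta2)``.  Vectorized over ``d``."""
    _check_theta(theta1, theta2)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    out = (1.0 - theta1) * np.exp(-d / theta2)
    out = np.where(d == 0.0, 1.0, out)
    return out if out.ndim else float(out)


def _check_theta(theta1: float, theta2: float) -> None:
    if not 0.0 <= theta1 <= 1.0:
        raise ValidationError(f"theta1={theta1} outside [0, 1]")
    if not theta2 > 0.0:
        raise ValidationError(f"theta2={theta2} must be positive")


def correlation_matrix(
    D: np.ndarray, theta1: float, theta2: float, jitter: float = 1e-8
) -> np.ndarray:
    """Correlation matrix Omega from a distance matrix.

    Unit diagonal by construction.  If the matrix is numerically non-PD
    (minimum eigenvalue below 1e-10 as detected by a failed Cholesky), jitter
    is added to the diagonal, the matrix renormalized to unit diagonal, and a
    warning emitted; if still non-PD a FittingError reports the minimum
    eigenvalue.  Exponential correlation on network distances is not
    guaranteed PD in general, hence the repair policy.
    """
    _check_theta(theta1, theta2)
    D = np.asarray(D, dtype=float)
    omega = (1.0 - theta1) * np.exp(-D / theta2)
    np.fill_diagonal(omega, 1.0)
    try:
        linalg.cholesky(omega, lower=True, check_finite=False)
        return omega
    except linalg.LinAlgError:
        pass
    warnings.warn("correlation matrix not positive definite; applying diagonal jitter")
    repaired = omega + jitter * np.eye(len(omega))
    repaired /= np.sqrt(np.outer(np.diag(repaired), np.diag(repaired)))
    try:
        linalg.cholesky(repaired, lower=True, check_finite=False)
        return repaired
    except linalg.LinAlgError:
        min_eig = float(np.linalg.eigvalsh(omega).min())
        raise FittingError(
            f"correlation matrix irreparably non-PD (min eigenvalue {min_eig:.3e})"
        ) from None


# --------------------------------------------------------------------------
# GLS estimators and likelihoods
# --------------------------------------------------------------------------

def _cholesky(omega: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(omega, lower=True, check_finite=False)
    except linalg.LinAlgError:
        min_eig = float(np.linalg.eigvalsh(omega).min())
        raise FittingError(
            f"correlation matrix not positive definite (min eigenvalue {min_eig:.3e})"
        ) from None


def _check_rank(X: np.ndarray, names: Optional[Sequence[str]] = None) -> None:
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        # identify offending columns via pivoted QR
        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(n, p) * np.finfo(float).eps
        bad = sorted(piv[diag < tol])
        labels = [names[j] if names else j for j in bad]
        raise FittingError(f"design matrix is rank deficient; collinear columns: {labels}")


def _gls_core(L: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Whitened GLS pieces given the Cholesky factor L of Omega."""
    Xw = linalg.solve_triangular(L, X, lower=True, check_finite=False)
    yw = linalg.solve_triangular(L, y, lower=True, check_finite=False)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    sigma2 = float(resid_w @ resid_w) / len(y)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, sigma2, logdet


def gls_beta(X: np.ndarray, y: np.ndarray, omega: np.ndarray,
             names: Optional[Sequence[str]] = None) -> np.ndarray:
    """GLS/ML coefficient estimate ``(X' Omega^-1 X)^-1 X' Omega^-1 Y``,
    computed through Cholesky solves (no explicit inverse)."""
    _check_rank(X, names)
    L = _cholesky(omega)
    beta, _, _ = _gls_core(L, X, y)
    return beta


def gls_sigma2(X: np.ndarray, y: np.ndarray, omega: np.ndarray, beta: np.ndarray) -> float:
    """ML variance estimate ``(Y-Xb)' Omega^-1 (Y-Xb) / n`` (divisor n)."""
    L = _cholesky(omega)
    resid = y - X @ beta
    rw = linalg.solve_triangular(L, resid, lower=True, check_finite=False)
    return float(rw @ rw) / len(y)


def log_likelihood(
    theta1: float, theta2: float, beta: np.ndarray, sigma2: float,
    X: np.ndarray, y: np.ndarray, D: np.ndarray,
) -> float:
    """Full Gaussian log-likelihood of (theta1, theta2, beta, sigma2)."""
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be positive")
    n = len(y)
    omega = correlation_matrix(D, theta1, theta2)
    L = _cholesky(omega)
    resid = y - X @ beta
    rw = linalg.solve_triangular(L, resid, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(
        -0.5 * n * _LOG2PI
        - 0.5 * (n * np.log(sigma2) + logdet)
        - 0.5 * (rw @ rw) / sigma2
    )


def profile_log_likelihood(
    theta1: float, theta2: float, X: np.ndarray, y: np.ndarray, D: np.ndarray
) -> float:
    """Profile log-likelihood at (theta1, theta2), with beta and sigma2
    replaced by their ML estimators."""
    omega = correlation_matrix(D, theta1, theta2)
    L = _cholesky(omega)
    _, sigma2, logdet = _gls_core(L, X, y)
    n = len(y)
    sigma2 = max(sigma2, 1e-300)  # guard the log for exactly-interpolating fits
    return float(-0.5 * n * _LOG2PI - 0.5 * n * np.log(sigma2) - 0.5 * logdet - 0.5 * n)


def profile_surface(
    X: np.ndarray, y: np.ndarray, D: np.ndarray,
    theta1_grid: Sequence[float], theta2_grid: Sequence[float],
) -> pd.DataFrame:
    """Exhaustive profile-likelihood evaluation on a (theta1, theta2) grid.

    Returns a long-format frame with columns theta1, theta2, profile_loglik,
    suitable for contour plotting.  The exp(-D/theta2) kernel is shared across
    theta1 values for each theta2.
    """
    if len(theta1_grid) == 0 or len(theta2_grid) == 0:
        raise ValidationError("theta grids must be non-empty")
    n = len(y)
    rows = []
    for t2 in theta2_grid:
        E = np.exp(-np.asarray(D, float) / t2)
        for t1 in theta1_grid:
            omega = (1.0 - t1) * E
            np.fill_diagonal(omega, 1.0)
            try:
                L = linalg.cholesky(omega, lower=True, check_finite=False)
            except linalg.LinAlgError:
                omega = correlation_matrix(D, t1, t2)
                L = _cholesky(omega)
            _, sigma2, logdet = _gls_core(L, X, y)
            sigma2 = max(sigma2, 1e-300)
            val = -0.5 * n * _LOG2PI - 0.5 * n * np.log(sigma2) - 0.5 * logdet - 0.5 * n
            rows.append((t1, t2, float(val)))
    return pd.DataFrame(rows, columns=["theta1", "theta2", "profile_loglik"])


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

class SpatialGLS(RegressorMixin, BaseEstimator):
    """Exponential-covariance spatial regression fitted by profile ML.

    Parameters
    ----------
    theta1, theta2 : float, optional
        If given, the correlation parameters are held fixed and only
        ``beta``/``sigma2`` are estimated.  By default both are estimated by
        maximizing the profile log-likelihood over a ``grid_size`` x
        ``grid_size`` grid (theta1 linear on [0, 1], theta2 log-spaced on
        ``theta2_bounds``) followed by L-BFGS-B refinement from the grid best.
    theta2_bounds : (float, float), optional
        Box for the range parameter in km; defaults to
        ``(1.0, 4 * max pairwise distance)``.
    n_neighbors : int
        Number of nearby monitoring sites used when kriging residuals in
        :meth:`predict`.
    refine : bool
        Whether to run local refinement after the grid search.

    Attributes
    ----------
    beta_, sigma2_, theta1_, theta2_, log_likelihood_ : fitted parameters
    residuals_ : ndarray, per-site ``y - X beta_``
    converged_ : bool, grid_best_ : (theta1, theta2, value) of the grid stage
    """

    def __init__(
        self,
        theta1: Optional[float] = None,
        theta2: Optional[float] = None,
        grid_size: int = 25,
        theta2_bounds: Optional[Tuple[float, float]] = None,
        n_neighbors: int = 8,
        refine: bool = True,
    ):
        self.theta1 = theta1
        self.theta2 = theta2
        self.grid_size = grid_size
        self.theta2_bounds = theta2_bounds
        self.n_neighbors = n_neighbors
        self.refine = refine

    # ------------------------------------------------------------------- fit
    def fit(self, X, y, D=None, feature_names: Optional[Sequence[str]] = None):
        """Fit to design matrix ``X`` (first column ones), response ``y``
        (LnTN scale) and the precomputed site distance matrix ``D`` (km)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if D is None:
            raise ValidationError("SpatialGLS.fit requires a precomputed distance matrix D")
        D = np.asarray(getattr(D, "values", D), dtype=float)
        n, p = X.shape
        if len(y) != n or D.shape != (n, n):
            raise ValidationError("X, y and D have inconsistent shapes")
        if n < p + 2:
            raise ValidationError(f"need at least p+2={p + 2} sites, got {n}")
        _check_rank(X, feature_names)

        self.feature_names_ = list(feature_names) if feature_names else None
        self.n_features_in_ = p
        self.X_, self.y_, self.D_ = X, y, D

        if self.theta1 is not None and self.theta2 is not None:
            t1, t2 = float(self.theta1), float(self.theta2)
            _check_theta(t1, t2)
            self.grid_best_ = None
            self.converged_ = True
        else:
            t1, t2 = self._optimize(X, y, D)

        omega = correlation_matrix(D, t1, t2)
        L = _cholesky(omega)
        beta, sigma2, _ = _gls_core(L, X, y)
        self.theta1_, self.theta2_ = float(t1), float(t2)
        self.beta_ = beta
        self.sigma2_ = float(sigma2)
        self.log_likelihood_ = profile_log_likelihood(t1, t2, X, y, D)
        self.residuals_ = y - X @ beta
        return self

    def _theta2_box(self, D: np.ndarray) -> Tuple[float, float]:
        if self.theta2_bounds is not None:
            lo, hi = self.theta2_bounds
        else:
            lo, hi = 1.0, 4.0 * float(D.max())
        if not 0 < lo < hi:
            raise ValidationError(f"invalid theta2 bounds ({lo}, {hi})")
        return lo, hi

    def _optimize(self, X, y, D) -> Tuple[float, float]:
        lo, hi = self._theta2_box(D)
        g = int(self.grid_size)
        t1_grid = np.linspace(0.0, 1.0, g)
        t2_grid = np.geomspace(lo, hi, g)
        surface = profile_surface(X, y, D, t1_grid, t2_grid)
        best = surface.loc[surface["profile_loglik"].idxmax()]
        t1b, t2b, vb = float(best["theta1"]), float(best["theta2"]), float(best["profile_loglik"])
        self.grid_best_ = (t1b, t2b, vb)
        if not self.refine:
            self.converged_ = True
            return t1b, t2b

        def neg(params):
            t1, t2 = params
            try:
                return -profile_log_likelihood(t1, t2, X, y, D)
            except FittingError:
                return np.inf

        res = optimize.minimize(
            neg, x0=[t1b, t2b], method="L-BFGS-B",
            bounds=[(0.0, 1.0), (lo, hi)],
        )
        self.converged_ = bool(res.success) or -res.fun >= vb
        if not np.isfinite(res.fun):
            raise FittingError(
                f"profile-likelihood refinement failed; grid best ({t1b:.3f}, {t2b:.1f}) "
                f"with value {vb:.4f}"
            )
        # the refined optimum must never fall below the grid best
        if -res.fun >= vb:
            return float(res.x[0]), float(res.x[1])
        return t1b, t2b

    # --------------------------------------------------------------- predict
    def predict(self, X, D_to_train=None, n_neighbors: Optional[int] = None):
        """Predict LnTN at target sites.

        ``X`` is the target design matrix (same columns as in :meth:`fit`).
        With ``D_to_train`` (targets x training sites distance matrix, km) the
        regression prediction is augmented by ordinary kriging of the training
        residuals over each target's nearest neighbors; without it the
        prediction is regression-only.
        """
        from .prediction import kriging_weights  # local import: avoid cycle

        X = np.asarray(X, dtype=float)
        yhat = X @ self.beta_
        if D_to_train is None:
            return yhat
        D0 = np.asarray(D_to_train, dtype=float)
        m = int(self.n_neighbors if n_neighbors is None else n_neighbors)
        m = min(m, len(self.y_))
        for i in range(len(yhat)):
            order = np.lexsort((np.arange(len(self.y_)), D0[i]))[:m]
            C = correlation_matrix(self.D_[np.ix_(order, order)], self.theta1_, self.theta2_)
            c0 = exponential_correlation(D0[i, order], self.theta1_, self.theta2_)
            lam, _ = kriging_weights(C, c0)
            yhat[i] += float(lam @ self.residuals_[order])
        return yhat


def fit_spatial(X, y, D, **params) -> SpatialGLS:
    """Functional wrapper: fit a :class:`SpatialGLS` and return it."""
    names = params.pop("feature_names", None)
    return SpatialGLS(**params).fit(X, y, D=D, feature_names=names)


class StepwiseLinearRegression(RegressorMixin, BaseEstimator):
    """Ordinary stepwise regression (forward entry, backward elimination).

    Entry and removal both use significance level ``alpha`` on the candidate's
    t-test p-value in the current model.  After fitting, OLS diagnostics are
    recorded: per-variable VIFs and the Breusch-Pagan heteroscedasticity test
    p-value, reported as advisory pass/fail flags (VIF < 10, p > 0.05).

    Attributes
    ----------
    selected_ : list of retained variable names
    intercept_, coef_ : fitted coefficients for the retained variables
    pvalues_ : mapping variable -> p-value in the final model
    rsquared_ : float
    vif_ : mapping variable -> variance inflation factor
    het_pvalue_ : Breusch-Pagan p-value (nan for an intercept-only model)
    diagnostics_ok_ : dict of advisory flags
    """

    def __init__(self, alpha: float = 0.05, max_steps: int = 100):
        self.alpha = alpha
        self.max_steps = max_steps

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        import statsmodels.api as sm
        from statsmodels.stats.diagnostic import het_breuschpagan
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, k = X.shape
        if k < 1:
            raise ValidationError("need at least one candidate variable")
        names = list(feature_names) if feature_names else [f"x{j}" for j in range(k)]

        def ols(cols):
            design = sm.add_constant(X[:, cols], has_constant="add")
            return sm.OLS(y, design).fit()

        selected: List[int] = []
        for _ in range(self.max_steps):
            changed = False
            # forward step: best candidate by p-value, enter if < alpha
            remaining = [j for j in range(k) if j not in selected]
            if remaining and len(selected) + 2 < n:
                pvals = {}
                for j in remaining:
                    res = ols(selected + [j])
                    pvals[j] = res.pvalues[-1]
                j_best = min(pvals, key=lambda j: (pvals[j], j))
                if pvals[j_best] < self.alpha:
                    selected.append(j_best)
                    changed = True
            # backward elimination: drop worst included variable while p > alpha
            while selected:
                res = ols(selected)
                worst_i = int(np.argmax(res.pvalues[1:]))
                if res.pvalues[1 + worst_i] > self.alpha:
                    del selected[worst_i]
                    changed = True
                else:
                    break
            if not changed:
                break

        res = ols(selected)
        self.selected_ = [names[j] for j in selected]
        self.selected_idx_ = list(selected)
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.pvalues_ = {names[j]: float(res.pvalues[1 + i]) for i, j in enumerate(selected)}
        self.rsquared_ = float(res.rsquared)
        self.sigma2_ = float(np.mean(res.resid**2))  # ML divisor n
        self.residuals_ = np.asarray(res.resid, dtype=float)
        self.results_ = res

        design = sm.add_constant(X[:, selected], has_constant="add")
        if selected:
            self.vif_ = {
                names[j]: float(variance_inflation_factor(design, 1 + i))
                for i, j in enumerate(selected)
            }
            self.het_pvalue_ = float(het_breuschpagan(res.resid, design)[1])
        else:
            self.vif_ = {}
            self.het_pvalue_ = float("nan")
        self.diagnostics_ok_ = {
            "vif_below_10": all(v < 10 for v in self.vif_.values()),
            "homoscedastic": (not selected) or self.het_pvalue_ > 0.05,
        }
        self.feature_names_ = names
        self.n_features_in_ = k
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X[:, self.selected_idx_] @ self.coef_


def stepwise_ols(candidates: pd.DataFrame, y, alpha: float = 0.05) -> StepwiseLinearRegression:
    """Functional wrapper: stepwise OLS over a candidate-variable frame."""
    return StepwiseLinearRegression(alpha=alpha).fit(candidates, y)
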