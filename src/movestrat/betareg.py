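"""Beta regression for proportion responses, with AICc and pseudo-R².

The overlap metrics are proportions in [0, 1], so candidate models are beta
regressions: ``y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi)`` with
``logit(mu_i) = x_i' beta`` and a constant precision ``phi``.  Observed
boundary values (exact 0s occur in the metrics) are compressed by the usual
``y' = (y * (n - 1) + 0.5) / n`` before fitting.  Maximum likelihood is
delegated to :class:`statsmodels.othermod.betareg.BetaModel`; this wrapper
adds the compression, small-sample AIC (AICc), Wald 95% intervals from the
observed-information inverse, and the conventional pseudo-R² (squared
Pearson correlation between ``logit(y')`` and the fitted linear predictor).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.othermod.betareg import BetaModel

Z95 = 1.959963984540054


def aicc(loglik: float, k_params: int, n: int) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1)."""
    if n - k_params - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k_params + 1}")
    return float(-2.0 * loglik + 2.0 * k_params
                 + 2.0 * k_params * (k_params + 1) / (n - k_params - 1))


def compress_boundary(y: np.ndarray) -> np.ndarray:
    """Map proportions off the boundary: (y*(n-1) + 0.5) / n."""
    y = np.asarray(y, float)
    n = y.size
    return (y * (n - 1) + 0.5) / n


class BetaRegression(RegressorMixin, BaseEstimator):
    """Beta regression with logit mean link and constant precision.

    ``fit(X, y)`` expects raw predictor columns (no intercept; one is added)
    and a proportion response in [0, 1].

    Attributes (after ``fit``): ``coef_`` (slopes), ``intercept_``,
    ``params_`` (intercept + slopes), ``phi_``, ``se_``, ``conf_int_``
    ((k, 2) Wald 95% bounds for intercept + slopes), ``loglik_``, ``aicc_``,
    ``pseudo_r2_``, ``n_``, ``k_params_``.
    """

    def __init__(self, compress: bool = True, max_restarts: int = 3):
        self.compress = compress
        self.max_restarts = max_restarts

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, float))
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
            X = X.T
        y = np.asarray(y, float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ValueError("X and y lengths differ")
        if np.nanmin(y) < 0 or np.nanmax(y) > 1:
            raise ValueError("response must lie in [0, 1]")
        Xd = np.column_stack([np.ones(n), X])
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            raise ValueError("design matrix is rank deficient")
        k = Xd.shape[1] + 1  # mean coefficients + precision
        if n <= k + 1:
            raise ValueError("too few observations for the parameter count")
        yc = compress_boundary(y) if self.compress else y
        if np.any(yc <= 0) or np.any(yc >= 1):
            raise ValueError("response on the boundary; enable compression")

        model = BetaModel(yc, Xd, exog_precision=np.ones((n, 1)))
        start = self._start_params(Xd, yc)

        def acceptable(r) -> bool:
            if not np.isfinite(r.params).all():
                return False
            score = model.score(r.params)
            return bool(np.max(np.abs(score)) < 1e-3 * max(1.0, abs(r.llf)))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(start_params=start, disp=0, maxiter=500)
            tries = 0
            while not acceptable(res) and tries < self.max_restarts:
                tries += 1
                res = model.fit(start_params=res.params, method="nm",
                                disp=0, maxiter=5000, xtol=1e-10, ftol=1e-10)
                res = model.fit(start_params=res.params, disp=0, maxiter=500)
        if not acceptable(res):
            raise RuntimeError(
                f"beta regression failed to converge after "
                f"{self.max_restarts} restarts: {res.mle_retvals}")

        # observed-information covariance, robust to statsmodels' own inversion
        hess = model.hessian(res.params)
        cov = -np.linalg.pinv(hess)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))

        mean_params = res.params[:-1]
        self.params_ = np.asarray(mean_params)
        self.intercept_ = float(mean_params[0])
        self.coef_ = np.asarray(mean_params[1:])
        self.phi_ = float(np.exp(res.params[-1]))
        self.se_ = se_all[:-1]
        self.conf_int_ = np.column_stack([self.params_ - Z95 * self.se_,
                                          self.params_ + Z95 * self.se_])
        self.loglik_ = float(res.llf)
        self.n_ = n
        self.k_params_ = k
        self.aicc_ = aicc(self.loglik_, k, n)
        eta = Xd @ mean_params
        if p == 0 or np.allclose(eta, eta[0]):
            self.pseudo_r2_ = 0.0
        else:
            r = np.corrcoef(logit(yc), eta)[0, 1]
            self.pseudo_r2_ = float(r ** 2)
        self._result_ = res
        return self

    @staticmethod
    def _start_params(Xd: np.ndarray, yc: np.ndarray) -> np.ndarray:
        """OLS of logit(y') for the mean part; moments for log(phi)."""
        z = logit(yc)
        beta0, *_ = np.linalg.lstsq(Xd, z, rcond=None)
        mu = expit(Xd @ beta0)
        resid_var = max(np.var(yc - mu), 1e-6)
        phi0 = np.clip(np.mean(mu * (1 - mu)) / resid_var - 1.0, 1.0, 1e4)
        return np.append(beta0, np.log(phi0))

    def predict(self, X) -> np.ndarray:
        """Fitted mean mu = logistic(intercept + X beta)."""
        check_is_fitted(self, "params_")
        X = np.atleast_2d(np.asarray(X, float))
        return expit(self.intercept_ + X @ self.coef_)


def fit_beta_regression(y, X) -> BetaRegression:
    """Fit a beta regression of proportions ``y`` on design columns ``X``.

    ``X`` may be an (n, p) array or an (n, 0)-shaped array / None for an
    intercept-only model.
    """
    y = np.asarray(y, float).ravel()
    if X is None:
        X = np.empty((y.size, 0))
    return BetaRegression().fit(np.asarray(X, float).reshape(y.size, -1), y)
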