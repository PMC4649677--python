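"""Log-link count regression of fecundity on pupal weight.

Implements the quasi-Poisson convention: Poisson maximum likelihood via
iteratively reweighted least squares gives the point estimates, and the
covariance is scaled by the Pearson chi-square dispersion estimate, so
overdispersion widens the standard errors without moving the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class RegressionFit:
    """Coefficients of fecundity = exp(a + b * weight) with quasi-type SEs."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    dispersion: float
    deviance_explained: float

    def __post_init__(self) -> None:
        if self.se_intercept < 0 or self.se_slope < 0:
            raise ValueError("standard errors must be non-negative")


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * float(np.sum(term - (y - mu)))


class WeightFecundityGLM(RegressorMixin, BaseEstimator):
    """Quasi-Poisson regression of egg counts on pupal weight (grams).

    Parameters
    ----------
    max_iter : int
        IRLS iteration cap.
    tol : float
        Convergence threshold on the relative deviance change.

    Attributes
    ----------
    intercept_ : float
        Estimated ``a`` in fecundity = exp(a + b * weight), log eggs.
    slope_ : float
        Estimated ``b``, log eggs per gram.
    se_intercept_, se_slope_ : float
        Quasi-Poisson standard errors (Pearson-dispersion scaled).
    dispersion_ : float
        Pearson chi-square / residual df.
    deviance_explained_ : float
        1 - residual deviance / null deviance.
    n_iter_ : int
        IRLS iterations used.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single column of pupal weights")
        y = np.asarray(y, dtype=float)
        n = len(y)
        if n != X.shape[0]:
            raise ValueError("X and y lengths differ")
        if n < 3:
            raise ValueError("need at least 3 observations")
        if np.any(y < 0):
            raise ValueError("fecundity counts must be non-negative")
        w = X[:, 0]
        if np.ptp(w) == 0:
            raise ValueError("slope unidentifiable: all weights identical")

        D = np.column_stack([np.ones(n), w])
        ybar = float(np.mean(y))
        if ybar <= 0:
            raise ValueError("all counts are zero; log-link mean undefined")
        beta = np.array([np.log(ybar), 0.0])
        dev = np.inf
        for it in range(1, self.max_iter + 1):
            eta = D @ beta
            mu = np.exp(np.clip(eta, -30, 30))
            z = eta + (y - mu) / mu
            WD = D * mu[:, None]
            beta_new = np.linalg.solve(D.T @ WD, WD.T @ z)
            dev_new = _poisson_deviance(y, np.exp(np.clip(D @ beta_new, -30, 30)))
            if not np.all(np.isfinite(beta_new)):
                raise RuntimeError("IRLS diverged: non-finite coefficients")
            beta = beta_new
            if abs(dev - dev_new) <= self.tol * (abs(dev_new) + 0.1):
                dev = dev_new
                break
            dev = dev_new
        else:
            raise RuntimeError(
                f"IRLS did not converge in {self.max_iter} iterations "
                f"(last deviance {dev:.6g})"
            )
        self.n_iter_ = it

        mu = np.exp(D @ beta)
        resid_df = max(n - 2, 1)
        pearson = float(np.sum((y - mu) ** 2 / mu))
        self.dispersion_ = pearson / resid_df
        cov = self.dispersion_ * np.linalg.inv(D.T @ (D * mu[:, None]))
        self.intercept_ = float(beta[0])
        self.slope_ = float(beta[1])
        self.coef_ = np.array([self.slope_])
        self.se_intercept_ = float(np.sqrt(cov[0, 0]))
        self.se_slope_ = float(np.sqrt(cov[1, 1]))
        null_dev = _poisson_deviance(y, np.full(n, ybar))
        self.deviance_ = dev
        self.null_deviance_ = null_dev
        self.deviance_explained_ = float(1.0 - dev / null_dev) if null_dev > 0 else 0.0
        return self

    def predict(self, X):
        check_is_fitted(self, "intercept_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return np.exp(self.intercept_ + self.slope_ * X[:, 0])

    def to_fit(self) -> RegressionFit:
        check_is_fitted(self, "intercept_")
        return RegressionFit(
            intercept=self.intercept_,
            slope=self.slope_,
            se_intercept=self.se_intercept_,
            se_slope=self.se_slope_,
            dispersion=self.dispersion_,
            deviance_explained=self.deviance_explained_,
        )
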