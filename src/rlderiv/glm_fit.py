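"""Subject-level GLM estimation.

Two fitting routes share one likelihood/BIC bookkeeping convention:

* :func:`ols_fit` -- ordinary least squares with Gaussian log-likelihood, used
  for the noiseless proof-of-concept simulations;
* :func:`ar2_fit` -- regression with AR(2) errors by exact Gaussian maximum
  likelihood, used for the fMRI-like simulations where the noise is strongly
  autocorrelated.  The likelihood is evaluated by quasi-differencing with the
  exact stationary initial-condition Cholesky factor, and profiled over the
  two AR partial autocorrelations (a bijective, automatically stationary
  parameterization), leaving a 2-D Nelder-Mead problem.

BIC counts k = (#regression coefficients) + (#AR coefficients) + 1 for the
innovation variance: bic = -2 loglik + k ln(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .design_regressors import znormalize

__all__ = ["DesignMatrix", "GLMFit", "ols_fit", "ar2_fit", "compare_bic"]


@dataclass
class DesignMatrix:
    """Named per-sample regressors plus a leading intercept column."""

    names: list[str]
    X: np.ndarray  # (n_samples, 1 + len(names)); column 0 is the intercept

    @classmethod
    def build(
        cls,
        columns: dict[str, np.ndarray],
        add_trend: bool = False,
        normalize: bool = True,
    ) -> "DesignMatrix":
        """Assemble [intercept | regressors (| trend)], z-normalizing each
        parametric column.  The linear trend is the standardized sample index."""
        cols = dict(columns)
        if add_trend:
            n = len(next(iter(cols.values())))
            cols["linear_trend"] = np.arange(n, dtype=float)
        names = list(cols)
        mats = []
        for name, col in cols.items():
            col = np.asarray(col, dtype=float)
            if np.ptp(col) == 0:
                raise ValueError(f"column {name!r} is constant")
            mats.append(znormalize(col) if normalize else col)
        X = np.column_stack([np.ones(len(mats[0]))] + mats)
        return cls(names=names, X=X)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.X))

    def to_frame(self):
        """One column per regressor (intercept first), one row per sample;
        write with ``.to_csv(path, sep='\\t')`` for inspection in any GLM tool."""
        import pandas as pd

        return pd.DataFrame(self.X, columns=["intercept"] + self.names)

    def drop(self, name: str) -> "DesignMatrix":
        """Design with one named column removed (for nested comparisons)."""
        idx = self.names.index(name)
        keep = [0] + [1 + i for i in range(len(self.names)) if i != idx]
        return DesignMatrix(
            names=[m for m in self.names if m != name], X=self.X[:, keep]
        )


@dataclass
class GLMFit:
    """Per-subject fit: coefficients, inference, likelihood and BIC."""

    names: list[str]  # includes 'intercept' first
    betas: np.ndarray
    tvalues: np.ndarray
    loglik: float
    bic: float
    sigma2: float
    nobs: int
    ar_coefficients: Optional[np.ndarray] = None
    converged: bool = True

    def beta(self, name: str) -> float:
        return float(self.betas[self.names.index(name)])

    def tvalue(self, name: str) -> float:
        return float(self.tvalues[self.names.index(name)])


def _check_rank(design: DesignMatrix) -> None:
    X = design.X
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < max(X.shape) * np.finfo(float).eps * diag.max()
    if bad.any():
        names = ["intercept"] + design.names
        culprits = [names[i] for i in np.nonzero(bad)[0]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {culprits}"
        )


def _gaussian_loglik(rss: float, n: int) -> tuple[float, float]:
    sigma2 = rss / n
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0), sigma2


def ols_fit(y, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares with intercept; Gaussian log-likelihood."""
    y = np.asarray(y, dtype=float)
    X = design.X
    n, k = X.shape
    if n <= k:
        raise ValueError("need more samples than columns")
    _check_rank(design)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    loglik, sigma2_ml = _gaussian_loglik(rss, n)
    s2 = rss / (n - k)
    se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
    k_bic = k + 1  # + innovation variance
    return GLMFit(
        names=["intercept"] + design.names,
        betas=beta,
        tvalues=beta / se,
        loglik=loglik,
        bic=-2.0 * loglik + k_bic * np.log(n),
        sigma2=sigma2_ml,
        nobs=n,
    )


def _ar2_transform(y: np.ndarray, X: np.ndarray, phi1: float, phi2: float):
    """Whiten (y, X) under stationary AR(2) errors with unit innovation SD.

    Rows >= 2 are quasi-differences; the first two rows are rotated by the
    inverse Cholesky factor of the stationary 2x2 covariance.  Returns the
    transformed pair and log|V| (V = error covariance / sigma2).
    """
    denom = (1 + phi2) * ((1 - phi2) ** 2 - phi1**2)
    if denom <= 1e-12:
        return None
    g0 = (1 - phi2) / denom
    g1 = phi1 * g0 / (1 - phi2)
    det_g = g0 * g0 - g1 * g1
    if det_g <= 0 or g0 <= 0:
        return None
    l11 = np.sqrt(g0)
    l21 = g1 / l11
    l22 = np.sqrt(g0 - l21 * l21)
    yt = np.empty_like(y)
    yt[0] = y[0] / l11
    yt[1] = (y[1] - l21 * yt[0]) / l22
    yt[2:] = y[2:] - phi1 * y[1:-1] - phi2 * y[:-2]
    Xt = np.empty_like(X)
    Xt[0] = X[0] / l11
    Xt[1] = (X[1] - l21 * Xt[0]) / l22
    Xt[2:] = X[2:] - phi1 * X[1:-1] - phi2 * X[:-2]
    return yt, Xt, float(np.log(det_g))


def _pacf_to_phi(params: np.ndarray) -> tuple[float, float]:
    r1, r2 = np.tanh(params)
    return float(r1 * (1.0 - r2)), float(r2)


def _ar2_profile_nll(params: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    phi1, phi2 = _pacf_to_phi(params)
    out = _ar2_transform(y, X, phi1, phi2)
    if out is None:
        return 1e12
    yt, Xt, logdet = out
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    loglik, _ = _gaussian_loglik(float(resid @ resid), len(y))
    return -(loglik - 0.5 * logdet)


def _yule_walker_start(resid: np.ndarray) -> np.ndarray:
    """Unconstrained start values (atanh of PACF) from OLS residuals."""
    c0 = float(resid @ resid)
    c1 = float(resid[1:] @ resid[:-1])
    c2 = float(resid[2:] @ resid[:-2])
    rho1, rho2 = c1 / c0, c2 / c0
    phi1 = rho1 * (1 - rho2) / (1 - rho1**2)
    phi2 = (rho2 - rho1**2) / (1 - rho1**2)
    r2 = float(np.clip(phi2, -0.9, 0.9))
    r1 = float(np.clip(phi1 / (1 - r2), -0.9, 0.9))
    return np.arctanh([r1, r2])


def ar2_fit(y, design: DesignMatrix) -> GLMFit:
    """Exact Gaussian ML for y = X beta + u, u_t = phi1 u_{t-1} + phi2 u_{t-2} + e_t.

    The likelihood is profiled over (phi1, phi2) via the partial
    autocorrelations; beta, t-values (conditional GLS), the exact
    log-likelihood and BIC (k = #beta + 2 + 1) are returned.  A fit that does
    not converge from the Yule-Walker start is retried from white-noise start
    values and flagged ``converged=False`` if both attempts fail.
    """
    y = np.asarray(y, dtype=float)
    X = design.X
    n, k = X.shape
    if n < 50:
        raise ValueError("AR(2) fit requires series length >= 50")
    _check_rank(design)
    beta0, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    x0 = _yule_walker_start(y - X @ beta0)
    res = minimize(
        _ar2_profile_nll,
        x0,
        args=(y, X),
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400},
    )
    if not res.success:
        retry = minimize(
            _ar2_profile_nll,
            np.zeros(2),
            args=(y, X),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 600},
        )
        if retry.fun < res.fun:
            res = retry
    phi1, phi2 = _pacf_to_phi(res.x)
    yt, Xt, logdet = _ar2_transform(y, X, phi1, phi2)
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    loglik_core, sigma2 = _gaussian_loglik(rss, n)
    loglik = loglik_core - 0.5 * logdet
    s2 = rss / (n - k)
    se = np.sqrt(s2 * np.diag(np.linalg.inv(Xt.T @ Xt)))
    k_bic = k + 2 + 1  # beta + AR(2) + innovation variance
    return GLMFit(
        names=["intercept"] + design.names,
        betas=beta,
        tvalues=beta / se,
        loglik=loglik,
        bic=-2.0 * loglik + k_bic * np.log(n),
        sigma2=sigma2,
        nobs=n,
        ar_coefficients=np.array([phi1, phi2]),
        converged=bool(res.success or res.fun < 1e11),
    )


def compare_bic(fit_reduced: GLMFit, fit_full: GLMFit) -> dict:
    """Nested model comparison by BIC; prefers_full iff bic_full < bic_reduced."""
    if fit_reduced.nobs != fit_full.nobs:
        raise ValueError("BIC comparison requires fits to the same series")
    delta = fit_reduced.bic - fit_full.bic
    return {"prefers_full": bool(delta > 0), "delta": float(delta)}
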