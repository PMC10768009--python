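"""Group-level statistics relating fitted betas to generative parameters.

Covers the whole validation battery: multiple-regression t-values, Pearson and
partial correlations, Cohen's d derived from r (d = 2r / sqrt(1 - r^2)),
z-tests for comparing two dependent overlapping correlations, Shrout-Fleiss
ICC(3,1) test-retest reliability, and the logistic regression explaining when
BIC prefers the fuller (RPE + derivative) subject-level model.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "regress_betas",
    "correlations",
    "d_from_r",
    "r_from_d",
    "compare_dependent_correlations",
    "icc_3_1",
    "bic_preference_logistic",
]


def regress_betas(
    table: pd.DataFrame, outcome_beta: str, predictors: list[str]
) -> pd.DataFrame:
    """OLS multiple regression of one beta column on generative parameters.

    Returns a tidy frame (one row per predictor) with coefficient, t value and
    residual degrees of freedom n - p - 1.
    """
    y = table[outcome_beta].to_numpy(dtype=float)
    for p in predictors:
        if table[p].nunique() < 2:
            raise ValueError(f"predictor {p!r} has no variance")
    X = sm.add_constant(table[predictors].to_numpy(dtype=float))
    if len(y) <= len(predictors) + 1:
        raise ValueError("need n > #predictors + 1")
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {
            "predictor": predictors,
            "coef": fit.params[1:],
            "t": fit.tvalues[1:],
            "p": fit.pvalues[1:],
            "df": int(fit.df_resid),
        }
    )


def _residualize_on(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), Z])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def correlations(
    table: pd.DataFrame, x: str, y: str, partial_out: list[str] | None = None
) -> float:
    """Pearson r, optionally partialling covariates out of both variables
    (double residualization, equivalent to the recursive partial-r formula)."""
    xv = table[x].to_numpy(dtype=float)
    yv = table[y].to_numpy(dtype=float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero-variance variable")
    if partial_out:
        Z = table[list(partial_out)].to_numpy(dtype=float)
        if len(xv) < 4 + Z.shape[1]:
            raise ValueError("too few observations for partial correlation")
        xv = _residualize_on(xv, Z)
        yv = _residualize_on(yv, Z)
    return float(stats.pearsonr(xv, yv).statistic)


def d_from_r(r: float) -> float:
    """Cohen's d equivalent of a point-biserial-style correlation: 2r/sqrt(1-r^2)."""
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return 2.0 * r / math.sqrt(1.0 - r * r)


def r_from_d(d: float) -> float:
    """Inverse of :func:`d_from_r`."""
    return d / math.sqrt(d * d + 4.0)


def compare_dependent_correlations(
    r_jk: float, r_jh: float, r_kh: float, n: int, method: str = "hittner2003"
) -> tuple[float, float]:
    """Two-sided z-test of H0: rho_jk = rho_jh for overlapping dependent
    correlations (variable j shared by both pairs).

    ``hittner2003`` is the Hittner-May-Silver modification of Dunn & Clark's z
    (the covariance term is evaluated at the Fisher back-transform of the mean
    of the two Fisher-transformed correlations); ``steiger1980`` evaluates it
    at the plain mean of the two correlations.  Returns (z, two-sided p).
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    for r in (r_jk, r_jh, r_kh):
        if abs(r) >= 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    det = (
        1 - r_jk**2 - r_jh**2 - r_kh**2 + 2 * r_jk * r_jh * r_kh
    )  # Gram determinant of the 3x3 correlation matrix
    if det < -1e-12:
        raise ValueError("infeasible correlation triple (not positive semi-definite)")
    z_jk = math.atanh(r_jk)
    z_jh = math.atanh(r_jh)
    if method == "hittner2003":
        r_bar = math.tanh((z_jk + z_jh) / 2.0)
    elif method == "steiger1980":
        r_bar = (r_jk + r_jh) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    rb2 = r_bar * r_bar
    cov = (r_kh * (1 - 2 * rb2) - 0.5 * rb2 * (1 - 2 * rb2 - r_kh**2)) / (1 - rb2) ** 2
    z = (z_jk - z_jh) * math.sqrt((n - 3) / (2.0 * (1.0 - cov)))
    return z, 2.0 * stats.norm.sf(abs(z))


def icc_3_1(scores: np.ndarray, ci_alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Shrout-Fleiss ICC(3,1): two-way mixed, consistency, single measure.

    ``scores`` is (n_participants, k_measures); here k is typically 2 blocks.
    ICC = (BMS - EMS) / (BMS + (k-1) EMS) with an F-based CI.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 3 or scores.shape[1] < 2:
        raise ValueError("scores must be (>=3 participants, >=2 measures)")
    n, k = scores.shape
    grand = scores.mean()
    row_means = scores.mean(axis=1)
    col_means = scores.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((scores - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms <= 0 and ems <= 0:
        raise ValueError("degenerate variance structure")
    icc = (bms - ems) / (bms + (k - 1) * ems)
    f_obs = bms / ems
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_u = stats.f.ppf(1 - ci_alpha / 2, df1, df2)
    f_l = stats.f.ppf(1 - ci_alpha / 2, df2, df1)
    fl = f_obs / f_u
    fu = f_obs * f_l
    ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    return float(icc), (float(ci[0]), float(ci[1]))


# Predictors of the BIC-preference logistic model; interactions are products
# of the z-scored main effects.
_LOGISTIC_MAINS = ["lam", "hrf_scale", "drift", "snr", "noise_exponent", "alpha_dist"]


def bic_preference_logistic(table: pd.DataFrame) -> pd.DataFrame:
    """Logistic regression of 'BIC prefers the RPE+derivative model'.

    Expects columns ``prefers_full`` (0/1), the generative parameters, and
    ``alpha`` (from which |alpha - 0.45| is formed).  All main effects are
    z-scored before interaction products with |alpha-0.45| are built.  Returns
    a tidy frame of coefficients with Wald z statistics.  On perfect
    separation, falls back to an L2-penalized fit with a warning.
    """
    y = table["prefers_full"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    work = table.copy()
    work["alpha_dist"] = (work["alpha"] - 0.45).abs()
    Z = {}
    for name in _LOGISTIC_MAINS:
        v = work[name].to_numpy(dtype=float)
        Z[name] = (v - v.mean()) / v.std()
    Z["alpha_dist_x_noise_exponent"] = Z["alpha_dist"] * Z["noise_exponent"]
    Z["alpha_dist_x_snr"] = Z["alpha_dist"] * Z["snr"]
    names = list(Z)
    X = sm.add_constant(np.column_stack([Z[name] for name in names]))
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0)
        params, tvalues, pvalues = fit.params, fit.tvalues, fit.pvalues
    except Exception:
        warnings.warn("perfect separation: falling back to L2-penalized logistic fit")
        fit = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        params = fit.params
        tvalues = np.full_like(params, np.nan)
        pvalues = np.full_like(params, np.nan)
    return pd.DataFrame(
        {
            "predictor": ["intercept"] + names,
            "coef": params,
            "wald_z": tvalues,
            "p": pvalues,
        }
    )
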