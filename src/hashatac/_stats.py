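"""Shared statistical helpers: BH adjustment, GLM wrappers, spline bases.

All generalized linear model fitting is delegated to statsmodels; this module
only fixes the conventions used across the pipeline (Wald tests on a named
coefficient, Pearson-based quasi dispersion, natural cubic spline bases).
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

#: coefficients beyond this magnitude after IRLS are treated as separated
SEPARATION_CAP = 15.0


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def natural_spline_basis(x, df: int = 3, *, design_info=None):
    """Natural cubic spline basis (no intercept column) for a 1-D covariate.

    The classical construction: boundary knots at the data range, interior
    knots at quantiles, basis = linear term plus truncated-power terms
    constrained to be linear beyond the boundaries, giving ``df`` columns
    that exclude the constant (full rank alongside an intercept).

    Returns ``(basis, knots)``; pass ``knots`` back via ``design_info`` to
    evaluate the same basis at new points (prediction grids).
    """
    x = np.asarray(x, dtype=float)
    if design_info is None:
        if df < 1:
            raise ValueError("df must be >= 1")
        n_knots = df + 1  # boundary pair + (df - 1) interior
        probs = np.linspace(0, 1, n_knots)
        knots = np.unique(np.quantile(x, probs))
        if len(knots) < 2:
            raise ValueError("covariate is constant; spline undefined")
    else:
        knots = np.asarray(design_info, dtype=float)
    K = len(knots)
    if K == 2:
        return x[:, None] - knots[0], knots

    def d(k, t):
        num = (np.clip(t - knots[k], 0, None) ** 3
               - np.clip(t - knots[-1], 0, None) ** 3)
        return num / (knots[-1] - knots[k])

    cols = [x - knots[0]]
    for k in range(K - 2):
        cols.append(d(k, x) - d(K - 2, x))
    return np.column_stack(cols), knots


def fit_logistic_wald(y, X, coef_index: int, maxiter: int = 100):
    """Logistic GLM fit; Wald z-test on one coefficient.

    Returns dict with beta, se, z, p, converged, separated, params.
    Zero-variance covariate columns (other than the intercept, assumed to be
    column 0) are dropped before fitting; the requested coefficient keeps its
    identity through the drop.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    if coef_index not in keep:
        return dict(beta=0.0, se=np.inf, z=0.0, p=1.0, converged=False,
                    separated=False, params=None)
    new_index = keep.index(coef_index)
    Xk = X[:, keep]
    try:
        res = sm.GLM(y, Xk, family=sm.families.Binomial()).fit(
            maxiter=maxiter, tol=1e-12)
    except Exception:
        return dict(beta=np.nan, se=np.nan, z=np.nan, p=np.nan,
                    converged=False, separated=True, params=None)
    beta = res.params[new_index]
    se = res.bse[new_index]
    separated = bool(np.any(np.abs(res.params) > SEPARATION_CAP))
    z = beta / se if se > 0 else np.nan
    p = res.pvalues[new_index]
    return dict(beta=float(beta), se=float(se), z=float(z), p=float(p),
                converged=bool(res.converged), separated=separated,
                params=res.params)


def fit_quasipoisson(y, X, coef_index: int, offset=None, maxiter: int = 100):
    """Quasipoisson (log link, Pearson dispersion) fit; test on one coefficient."""
    res = sm.GLM(
        np.asarray(y, dtype=float), np.asarray(X, dtype=float),
        family=sm.families.Poisson(), offset=offset,
    ).fit(maxiter=maxiter, tol=1e-12, scale="X2")
    beta = res.params[coef_index]
    se = res.bse[coef_index]
    z = beta / se if se > 0 else np.nan
    return dict(beta=float(beta), se=float(se), z=float(z),
                p=float(res.pvalues[coef_index]), params=res.params,
                scale=float(res.scale))


def fit_negative_binomial(y, X, *, alpha=None, offset=None, maxiter: int = 100,
                          tol: float = 1e-12, outer_iter: int = 25):
    """Negative-binomial (NB2) log-link GLM.

    If ``alpha`` is given it is held fixed. Otherwise alpha is estimated by
    iterating a Pearson moment estimator around fixed-alpha GLM fits, starting
    from a Poisson fit; alpha is floored at 1e-8 (Poisson limit).
    Returns the statsmodels results object with ``nb_alpha`` attached.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if alpha is not None:
        res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                     offset=offset).fit(maxiter=maxiter, tol=tol)
        res.nb_alpha = float(alpha)
        return res
    res = sm.GLM(y, X, family=sm.families.Poisson(),
                 offset=offset).fit(maxiter=maxiter)
    a = 1e-8
    df_resid = max(len(y) - X.shape[1], 1)
    for _ in range(outer_iter):
        mu = res.fittedvalues
        # Pearson moment estimate of NB2 dispersion: E[(y-mu)^2] = mu + a*mu^2
        a_new = float(np.sum(((y - mu) ** 2 - mu) / mu**2) / df_resid)
        a_new = max(a_new, 1e-8)
        if abs(a_new - a) < 1e-6 * (a + 1e-6):
            a = a_new
            break
        a = a_new
        res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=a),
                     offset=offset).fit(maxiter=maxiter, tol=tol)
    res.nb_alpha = a
    return res


def gaussian_lrt(y, X_full, X_reduced):
    """Likelihood-ratio test between nested Gaussian (OLS) models.

    Returns (statistic, df, p, full_results, reduced_results); statistic is
    2*(llf_full - llf_reduced), df the column-count difference.
    """
    from scipy import stats

    full = sm.OLS(np.asarray(y, dtype=float), np.asarray(X_full, float)).fit()
    red = sm.OLS(np.asarray(y, dtype=float), np.asarray(X_reduced, float)).fit()
    stat = 2.0 * (full.llf - red.llf)
    df = X_full.shape[1] - X_reduced.shape[1]
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return float(stat), int(df), p, full, red
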