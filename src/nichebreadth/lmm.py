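"""Mixed-effects hypothesis tests for how populations accrue niche breadth.

Three linear mixed models, each regressing population-level thermal breadth
on one predictor, with a random intercept per species pair to absorb the
shared evolutionary history of the two populations in a pair:

- H1 "generalist": predictor = family-level T_breadth (one observation per
  family; broad genotypes make broad populations).
- H2 "divergent optima": predictor = among-family variance in T_opt (one
  observation per population; specialized genotypes with divergent optima).
- H3 "breadth variation": predictor = among-family variance in T_breadth
  (one observation per population).

Estimation is REML (statsmodels MixedLM). The fixed-effect covariance is
recomputed by generalized least squares at the REML variance components,
C = (X' V^-1 X)^-1 with V = sigma2*I + tau2*Z Z', which matches lme4's
standard errors; p-values are two-sided Wald t with Satterthwaite
degrees of freedom computed from the curvature of the REML log-likelihood
in (tau2, sigma2). A slope is called significant when it is positive and
its one-sided p (= p/2) falls below alpha = .1, the decision rule used for
these hypotheses. Marginal and conditional R^2 follow the Nakagawa
variance-partition formulation. Standardized fits z-score response and
predictor across all observations first, making slopes comparable across
the three models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .tpc import ParameterError

__all__ = ["LmmResult", "fit_pair_lmm", "standardize_and_fit", "run_all_models", "MODEL_IDS"]

MODEL_IDS = ("H1_generalist", "H2_divergent_optima", "H3_breadth_variation")

_MODEL_PREDICTOR = {
    "H1_generalist": "family_tbreadth",
    "H2_divergent_optima": "var_topt",
    "H3_breadth_variation": "var_tbreadth",
}


@dataclass(frozen=True)
class LmmResult:
    """One hypothesis model's fit (raw scale, plus standardized slope)."""

    model: str
    slope: float
    slope_se: float
    p_value: float
    df: float
    marginal_r2: float
    conditional_r2: float
    n_obs: int
    n_groups: int
    tau2: float
    sigma2: float
    intercept: float
    standardized_slope: float | None = None
    standardized_se: float | None = None

    def significant(self, alpha: float = 0.1) -> bool:
        """One-sided call: slope > 0 and p/2 < alpha."""
        return self.slope > 0 and (self.p_value / 2.0) < alpha


def _reml_loglik(theta, y, X, groups_idx, n_groups):
    """REML log-likelihood of the random-intercept model at theta=(tau2, sigma2)."""
    tau2, sigma2 = theta
    if sigma2 <= 0 or tau2 < 0:
        return -np.inf
    n = len(y)
    # V = sigma2*I + tau2*Z Z' is block diagonal; use Woodbury per group
    log_det_v = 0.0
    XtVinvX = np.zeros((X.shape[1], X.shape[1]))
    XtVinvy = np.zeros(X.shape[1])
    ytVinvy = 0.0
    for g in range(n_groups):
        sel = groups_idx == g
        ng = int(sel.sum())
        Xg, yg = X[sel], y[sel]
        # V_g^-1 = (1/sigma2)(I - tau2/(sigma2 + ng*tau2) * J)
        denom = sigma2 + ng * tau2
        log_det_v += (ng - 1) * np.log(sigma2) + np.log(denom)
        def vinv_dot(M):
            return (M - (tau2 / denom) * np.outer(np.ones(ng), M.sum(axis=0))) / sigma2
        VinvX = vinv_dot(Xg)
        Vinvy = vinv_dot(yg[:, None])[:, 0]
        XtVinvX += Xg.T @ VinvX
        XtVinvy += Xg.T @ Vinvy
        ytVinvy += yg @ Vinvy
    beta = np.linalg.solve(XtVinvX, XtVinvy)
    quad = ytVinvy - XtVinvy @ beta
    sign, log_det_xvx = np.linalg.slogdet(XtVinvX)
    p = X.shape[1]
    return -0.5 * (
        log_det_v + log_det_xvx + quad + (n - p) * np.log(2.0 * np.pi)
    )


def _gls_cov(theta, X, groups_idx, n_groups):
    """(X' V^-1 X)^-1 at theta=(tau2, sigma2)."""
    tau2, sigma2 = theta
    XtVinvX = np.zeros((X.shape[1], X.shape[1]))
    for g in range(n_groups):
        sel = groups_idx == g
        ng = int(sel.sum())
        Xg = X[sel]
        denom = sigma2 + ng * tau2
        VinvX = (Xg - (tau2 / denom) * np.outer(np.ones(ng), Xg.sum(axis=0))) / sigma2
        XtVinvX += Xg.T @ VinvX
    return np.linalg.inv(XtVinvX)


def _satterthwaite_df(theta, y, X, groups_idx, n_groups, contrast):
    """Satterthwaite df for l'beta: 2*f^2 / (grad f' A grad f).

    f(theta) = l' C(theta) l, A = inverse observed REML information. Falls
    back to the residual df when the information matrix is degenerate (e.g.
    at the tau2 = 0 boundary).
    """
    n, p = X.shape
    resid_df = float(n - p)
    l = np.asarray(contrast, dtype=float)

    def f(th):
        return float(l @ _gls_cov(th, X, groups_idx, n_groups) @ l)

    h = np.maximum(1e-5 * np.maximum(np.abs(theta), 1.0), 1e-8)
    grad = np.zeros(2)
    for j in range(2):
        e = np.zeros(2)
        e[j] = h[j]
        lo = np.maximum(theta - e, [0.0, 1e-12])
        grad[j] = (f(theta + e) - f(lo)) / (theta[j] + h[j] - lo[j])

    def nll(th):
        return -_reml_loglik(th, y, X, groups_idx, n_groups)

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei, ej = np.zeros(2), np.zeros(2)
            ei[i], ej[j] = h[i], h[j]
            H[i, j] = (
                nll(theta + ei + ej) - nll(theta + ei) - nll(theta + ej) + nll(theta)
            ) / (h[i] * h[j])
    try:
        A = np.linalg.inv(0.5 * (H + H.T))
    except np.linalg.LinAlgError:
        return resid_df
    denom = float(grad @ A @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return resid_df
    df = 2.0 * f(theta) ** 2 / denom
    if not np.isfinite(df) or df <= 0:
        return resid_df
    return float(min(df, resid_df * 10.0))


def fit_pair_lmm(y, x, pair, model: str = "custom") -> LmmResult:
    """REML random-intercept-per-pair regression of ``y`` on ``x``.

    Returns the fixed slope with its GLS standard error, a Satterthwaite
    two-sided Wald-t p-value, the variance components, and Nakagawa
    marginal/conditional R^2. A singular fit (pair variance estimated at
    zero) is allowed and reported with ``tau2 = 0``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    pair = np.asarray(pair)
    if y.shape != x.shape or y.shape != pair.shape:
        raise ParameterError("y, x and pair must have equal lengths")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(x)):
        raise ParameterError("y and x must be finite")
    groups, groups_idx = np.unique(pair, return_inverse=True)
    if len(groups) < 2:
        raise ParameterError("need >= 2 pairs (groups)")
    if np.ptp(x) == 0:
        raise ParameterError("predictor is constant; slope undefined")

    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # singular-fit convergence chatter
        fit = MixedLM(y, X, groups=groups_idx).fit(reml=True)
    tau2 = max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)
    sigma2 = float(fit.scale)
    theta = np.array([tau2, sigma2])

    # fixed-effect covariance by GLS at the REML variance components; this
    # is the standard (X'V^-1 X)^-1 form rather than statsmodels' profiled
    # approximation, and matches the reference mixed-model implementations
    C = _gls_cov(theta, X, groups_idx, len(groups))
    beta = np.asarray(fit.fe_params)
    se = float(np.sqrt(C[1, 1]))
    df = _satterthwaite_df(theta, y, X, groups_idx, len(groups), contrast=[0.0, 1.0])
    t_stat = beta[1] / se
    p = float(2.0 * sp_stats.t.sf(abs(t_stat), df))

    fixed = X @ beta
    var_fixed = float(np.var(fixed, ddof=1))
    denom = var_fixed + tau2 + sigma2
    return LmmResult(
        model=model,
        slope=float(beta[1]),
        slope_se=se,
        p_value=p,
        df=df,
        marginal_r2=var_fixed / denom,
        conditional_r2=(var_fixed + tau2) / denom,
        n_obs=len(y),
        n_groups=len(groups),
        tau2=tau2,
        sigma2=sigma2,
        intercept=float(beta[0]),
    )


def standardize_and_fit(y, x, pair, model: str = "custom") -> LmmResult:
    """Z-score ``y`` and ``x`` across all observations, then fit.

    The resulting slope is comparable across predictors with different
    units; in the no-pair-structure limit it equals the sample correlation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    sy, sx = np.std(y, ddof=1), np.std(x, ddof=1)
    if sy == 0 or sx == 0:
        raise ParameterError("cannot standardize a zero-variance variable")
    return fit_pair_lmm((y - y.mean()) / sy, (x - x.mean()) / sx, pair, model=model)


def run_all_models(
    summaries: pd.DataFrame,
    family_breadths: pd.DataFrame | None = None,
    alpha: float = 0.1,
) -> Dict[str, LmmResult]:
    """Fit the three hypothesis models (raw + standardized slopes).

    ``summaries`` is a summary-table DataFrame (one row per population,
    columns population, pair, pop_tbreadth, var_topt, var_tbreadth).
    ``family_breadths`` (columns population, family, family_tbreadth)
    supplies the per-family observations of the generalist model; each
    family enters unweighted with its population's breadth as response. If
    absent, that model is skipped with a warning.
    """
    results: Dict[str, LmmResult] = {}
    pop_cols = summaries.set_index("population")

    if family_breadths is not None:
        fb = family_breadths[["population", "family", "family_tbreadth"]].merge(
            summaries[["population", "pair", "pop_tbreadth"]], on="population"
        )
        y, x, g = fb["pop_tbreadth"], fb["family_tbreadth"], fb["pair"]
        raw = fit_pair_lmm(y, x, g, model="H1_generalist")
        std = standardize_and_fit(y, x, g, model="H1_generalist")
        results["H1_generalist"] = replace(
            raw, standardized_slope=std.slope, standardized_se=std.slope_se
        )
    else:
        warnings.warn(
            "no per-family breadths supplied; generalist model skipped",
            RuntimeWarning,
            stacklevel=2,
        )

    for model in ("H2_divergent_optima", "H3_breadth_variation"):
        pred = _MODEL_PREDICTOR[model]
        y, x, g = summaries["pop_tbreadth"], summaries[pred], summaries["pair"]
        raw = fit_pair_lmm(y, x, g, model=model)
        std = standardize_and_fit(y, x, g, model=model)
        results[model] = replace(
            raw, standardized_slope=std.slope, standardized_se=std.slope_se
        )
    return results
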