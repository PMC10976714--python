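"""Two-level random-intercept mixed model, ICC, and robustness fits.

The primary fit is a linear mixed model with a random intercept at the
grouping level (REML by default), reported with cluster-robust standard
errors and the intra-class correlation ICC = s_u^2 / (s_u^2 + s_e^2).
Within-grouping fixed-effects and pooled-OLS fits mirror the usual
three-column robustness layout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

_BOUNDARY_TOL = 1e-8


@dataclass(frozen=True)
class MixedModelResult:
    params: pd.Series            # intercept + slopes
    se: pd.Series                # cluster-robust at grouping level
    sigma_u2: float              # random-intercept variance
    sigma_e2: float              # residual variance
    icc: float
    loglike: float
    lr_stat: float               # 2*(ML loglike - pooled-OLS loglike)
    lr_pvalue: float             # boundary-corrected (0.5*chi2_1 mixture)
    method: str                  # "REML" | "ML"
    boundary: bool               # sigma_u2 estimated at the zero boundary
    n_groups: int
    n_obs: int

    def table(self) -> pd.DataFrame:
        z = self.params / self.se
        return pd.DataFrame({
            "coef": self.params,
            "se": self.se,
            "z": z,
            "pvalue": 2 * stats.norm.sf(np.abs(z)),
        })


def _design(data: pd.DataFrame, outcome: str, covariates, grouping: str):
    cols = [outcome, grouping, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns not in data: {missing}")
    frame = data[cols].copy()
    if frame.isna().any().any():
        raise ValueError("modeling frame contains missing cells")
    y = frame[outcome].to_numpy(dtype=float)
    X = sm.add_constant(frame[list(covariates)].astype(float), has_constant="add")
    groups = frame[grouping].astype(str)
    return y, X, groups


def fit_mixed(data: pd.DataFrame, outcome: str, covariates, grouping: str,
              reml: bool = True, robust: bool = True) -> MixedModelResult:
    """Random-intercept linear mixed model, grouping as the cluster level.

    A sigma_u^2 estimate at the zero boundary is returned with the
    ``boundary`` flag set rather than raised.  ``robust=False`` falls back
    to model-based standard errors.
    """
    y, X, groups = _design(data, outcome, covariates, grouping)
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groupings for a random intercept")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits warn about convergence
        model = sm.MixedLM(y, X, groups=groups)
        fit = model.fit(reml=reml, method=["lbfgs", "powell"])
    sigma_u2 = float(fit.cov_re.iloc[0, 0])
    sigma_e2 = float(fit.scale)
    boundary = sigma_u2 <= _BOUNDARY_TOL
    if boundary:
        # at sigma_u2 = 0 the model collapses to pooled OLS exactly;
        # statsmodels' GLS step is unreliable on the singular boundary
        log.info("random-intercept variance at the zero boundary")
        ols_fit = sm.OLS(y, X).fit()
        sigma_u2 = 0.0
        sigma_e2 = float(ols_fit.scale)
        params = pd.Series(np.asarray(ols_fit.params), index=X.columns)
    else:
        params = pd.Series(np.asarray(fit.fe_params), index=X.columns)
    if robust:
        se = _cluster_robust_se_mixed(y, X.to_numpy(), groups.to_numpy(),
                                      params.to_numpy(), sigma_u2, sigma_e2)
        se = pd.Series(se, index=X.columns)
    else:
        se = pd.Series(np.asarray(fit.bse_fe), index=X.columns)
    # LR against pooled OLS uses ML loglikelihoods (nested comparison)
    if reml:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ml_fit = sm.MixedLM(y, X, groups=groups).fit(
                reml=False, method=["lbfgs", "powell"])
        ml_llf = float(ml_fit.llf)
    else:
        ml_llf = float(fit.llf)
    ols_llf = float(sm.OLS(y, X).fit().llf)
    lr = max(0.0, 2.0 * (ml_llf - ols_llf))
    # null sigma_u2 = 0 is on the boundary: 0.5*chi2_0 + 0.5*chi2_1 mixture
    lr_p = 0.5 * stats.chi2.sf(lr, df=1) if lr > 0 else 1.0
    denom = sigma_u2 + sigma_e2
    return MixedModelResult(
        params=params,
        se=se,
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        icc=sigma_u2 / denom if denom > 0 else 0.0,
        loglike=float(fit.llf),
        lr_stat=lr,
        lr_pvalue=float(lr_p),
        method="REML" if reml else "ML",
        boundary=boundary,
        n_groups=int(groups.nunique()),
        n_obs=len(y),
    )


def _cluster_robust_se_mixed(y, X, groups, beta, sigma_u2, sigma_e2):
    """Sandwich SEs for the GLS fixed effects of a random-intercept model.

    Uses the Woodbury form of V_j^-1 for V_j = s_e^2 I + s_u^2 J, so no
    per-cluster matrix inversion is needed.
    """
    labels = pd.unique(groups)
    k = X.shape[1]
    bread = np.zeros((k, k))
    meat = np.zeros((k, k))
    for g in labels:
        idx = groups == g
        Xg, rg = X[idx], y[idx] - X[idx] @ beta
        n_g = Xg.shape[0]
        c = sigma_u2 / (sigma_e2 + n_g * sigma_u2)
        # V^-1 x = (x - c * sum(x)) / sigma_e2
        Vinv_X = (Xg - c * Xg.sum(axis=0)) / sigma_e2
        Vinv_r = (rg - c * rg.sum()) / sigma_e2
        bread += Xg.T @ Vinv_X
        s = Xg.T @ Vinv_r
        meat += np.outer(s, s)
    bread_inv = np.linalg.inv(bread)
    G = len(labels)
    adj = G / (G - 1.0) if G > 1 else 1.0
    cov = adj * bread_inv @ meat @ bread_inv
    return np.sqrt(np.diag(cov))


def icc(res_or_sigma_u2, sigma_e2: float | None = None) -> float:
    """Intra-class correlation sigma_u^2 / (sigma_u^2 + sigma_e^2)."""
    if isinstance(res_or_sigma_u2, MixedModelResult):
        return res_or_sigma_u2.icc
    sigma_u2 = float(res_or_sigma_u2)
    if sigma_u2 < 0 or sigma_e2 is None or sigma_e2 <= 0:
        raise ValueError("need sigma_u2 >= 0 and sigma_e2 > 0")
    return sigma_u2 / (sigma_u2 + sigma_e2)


def fit_fixed_effects(data: pd.DataFrame, outcome: str, covariates,
                      grouping: str) -> pd.DataFrame:
    """Within-grouping demeaning then OLS with cluster-robust SEs.

    Covariates constant within every grouping are dropped with a warning;
    a single grouping is rejected (nothing to demean against would leave
    pooled OLS in disguise).
    """
    y, X, groups = _design(data, outcome, covariates, grouping)
    if groups.nunique() < 2:
        raise ValueError("fixed-effects fit needs at least 2 groupings")
    X = X.drop(columns="const")
    keep = []
    for c in X.columns:
        if X.groupby(groups.to_numpy())[c].nunique().le(1).all():
            log.warning("covariate %s constant within all groupings; dropped", c)
        else:
            keep.append(c)
    if not keep:
        raise ValueError("no covariate varies within groupings")
    Xd = X[keep] - X[keep].groupby(groups.to_numpy()).transform("mean")
    yd = y - pd.Series(y).groupby(groups.to_numpy()).transform("mean").to_numpy()
    fit = sm.OLS(yd, Xd).fit(cov_type="cluster",
                             cov_kwds={"groups": groups.to_numpy()})
    return pd.DataFrame({
        "coef": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "pvalue": fit.pvalues,
    })


def fit_pooled_ols(data: pd.DataFrame, outcome: str, covariates,
                   grouping: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Pooled OLS with heteroskedasticity-robust (HC1) standard errors.

    Returns the coefficient table and a stats dict (r2, F, its p-value,
    nobs).  Rank deficiency is an error naming the collinear columns.
    """
    cols = [outcome, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns not in data: {missing}")
    frame = data[cols].dropna()
    y = frame[outcome].to_numpy(dtype=float)
    X = sm.add_constant(frame[list(covariates)].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = _collinear_columns(X)
        raise ValueError(f"design matrix is rank deficient; check columns {collinear}")
    fit = sm.OLS(y, X).fit(cov_type="HC1")
    table = pd.DataFrame({
        "coef": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "pvalue": fit.pvalues,
    })
    info = {
        "r2": float(fit.rsquared),
        "f_stat": float(fit.fvalue) if fit.df_model > 0 else np.nan,
        "f_pvalue": float(fit.f_pvalue) if fit.df_model > 0 else np.nan,
        "nobs": int(fit.nobs),
        "loglike": float(fit.llf),
    }
    return table, info


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    bad = []
    for c in X.columns:
        if c == "const":
            continue
        others = X.drop(columns=c)
        if np.linalg.matrix_rank(others.to_numpy()) == np.linalg.matrix_rank(X.to_numpy()):
            bad.append(c)
    return bad
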