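"""Relative transition paths and the log-t convergence regression.

The test works off the cross-sectional variance H_t of the relative
transition parameter h_it = X_it / cross-sectional-mean(X_t).  Under
convergence H_t decays to zero, and the trimmed regression

    log(H_1 / H_t) - 2 log L(t) = Q + gamma * log t ,  t = t0..T

with L(t) = log t and t0 = max(2, floor(r*T)) has slope gamma = 2a
(twice the decay speed).  Convergence is rejected one-sided when the
HAC t-statistic of gamma falls below the critical value (default -1.65).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from clubconv.panel import PanelSeries

DEFAULT_TRIM = 0.3
DEFAULT_CRITICAL = -1.65


class DegeneratePanelError(ValueError):
    """H_t vanished where the regression needs it.

    ``where`` distinguishes a panel that is identical on the regression
    window (``"window"`` — trivially converged) from one whose units
    coincide only at t = 1 (``"start"`` — the variance ratio H_1/H_t is
    undefined because its numerator is zero).
    """

    def __init__(self, message: str, where: str = "window"):
        super().__init__(message)
        self.where = where


@dataclass(frozen=True)
class TransitionResult:
    """Relative transition parameters and their cross-sectional variance."""

    h: np.ndarray  # (N, T): unit value / cross-sectional mean
    H: np.ndarray  # (T,): mean over units of (h - 1)^2


@dataclass(frozen=True)
class LogtResult:
    """Fitted log-t regression with one-sided HAC inference."""

    gamma_hat: float
    intercept: float
    se_gamma: float
    t_gamma: float
    r: float
    window: tuple[int, int]
    critical: float
    converged: bool
    residuals: np.ndarray
    hac_lags: int
    n_units: int

    def to_dict(self) -> dict:
        return {
            "gamma_hat": self.gamma_hat,
            "intercept": self.intercept,
            "se_gamma": self.se_gamma,
            "t_gamma": self.t_gamma,
            "r": self.r,
            "window": list(self.window),
            "critical": self.critical,
            "converged": self.converged,
            "hac_lags": self.hac_lags,
            "n_units": self.n_units,
        }


def relative_transition(p: PanelSeries) -> TransitionResult:
    """h_it = X_it / (N^-1 sum_i X_it) and H_t = N^-1 sum_i (h_it - 1)^2."""
    X = p.values
    mean = X.mean(axis=0)
    if np.any(np.isclose(mean, 0.0)):
        t_bad = [int(t) for t in p.times[np.isclose(mean, 0.0)]]
        raise ValueError(f"cross-sectional mean is zero at t={t_bad}; h undefined")
    h = X / mean
    H = ((h - 1.0) ** 2).mean(axis=0)
    return TransitionResult(h=h, H=H)


def default_hac_lags(n_obs: int) -> int:
    """Newey-West rule-of-thumb bandwidth floor(4 * (n/100)^(2/9))."""
    return int(np.floor(4.0 * (n_obs / 100.0) ** (2.0 / 9.0)))


def logt_regression(p: PanelSeries, r: float = DEFAULT_TRIM,
                    hac_lags: int | None = None,
                    critical: float = DEFAULT_CRITICAL,
                    slow_var: str = "log") -> LogtResult:
    """One-sided log-t convergence test on a balanced panel.

    Parameters
    ----------
    p : PanelSeries
        Balanced panel (typically log-scale values).
    r : float
        Trimming fraction; the regression runs on t = max(2, floor(r*T))..T.
    hac_lags : int, optional
        Bartlett-kernel (Newey-West) bandwidth; default is the
        floor(4*(n/100)^(2/9)) rule on the window length.
    critical : float
        One-sided critical value; convergence holds iff t_gamma > critical.
    slow_var : {"log", "log1p"}
        Penalty function L(t): log t (default) or log(t + 1).
    """
    if not 0 < r < 1:
        raise ValueError("trimming fraction r must be in (0, 1)")
    T = p.n_periods
    t0 = max(2, int(np.floor(r * T)))
    if T - t0 + 1 < 3:
        raise ValueError(
            f"trimmed window [{t0}, {T}] has fewer than 3 points; panel too short"
        )
    H = relative_transition(p).H
    t = np.arange(t0, T + 1)
    if np.any(H[t - 1] <= 0):
        raise DegeneratePanelError(
            "H_t is zero on the regression window (units identical there); "
            "log-t regressand undefined", where="window",
        )
    if H[0] <= 0:
        raise DegeneratePanelError(
            "H_1 is zero (units coincide at t=1); the variance ratio "
            "H_1/H_t is undefined", where="start",
        )
    if slow_var == "log":
        L = np.log(t)
    elif slow_var == "log1p":
        L = np.log(t + 1.0)
    else:
        raise ValueError(f"unknown slow_var {slow_var!r}")
    y = np.log(H[0] / H[t - 1]) - 2.0 * np.log(L)
    x = sm.add_constant(np.log(t))
    lags = default_hac_lags(len(t)) if hac_lags is None else int(hac_lags)
    fit = sm.OLS(y, x).fit(cov_type="HAC", cov_kwds={"maxlags": lags})
    gamma, q = float(fit.params[1]), float(fit.params[0])
    se = float(fit.bse[1])
    if se > 0:
        t_gamma = gamma / se
    else:  # exact fit: degenerate SE, sign of gamma decides
        t_gamma = float(np.inf) if gamma >= 0 else float(-np.inf)
    return LogtResult(
        gamma_hat=gamma,
        intercept=q,
        se_gamma=se,
        t_gamma=t_gamma,
        r=r,
        window=(int(t0), int(T)),
        critical=critical,
        converged=bool(t_gamma > critical),
        residuals=np.asarray(fit.resid),
        hac_lags=lags,
        n_units=p.n_units,
    )


def logt_report(res: LogtResult, label: str = "") -> dict:
    """Flat coefficient / SE / t-stat record for table output."""
    return {
        "label": label,
        "coeff": round(res.gamma_hat, 3),
        "se": round(res.se_gamma, 3),
        "t_stat": round(res.t_gamma, 3) if np.isfinite(res.t_gamma) else res.t_gamma,
        "converged": res.converged,
    }
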