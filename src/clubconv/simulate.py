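"""Seeded synthetic-data generators.

Two generators back the test surface of the whole package:

* :func:`simulate_panel` draws balanced panels from the semi-parametric
  loading process X_it = delta_it * mu_t with
  delta_it = delta_i + theta_i * e_it / (L(t) * t^a), e_it iid standard
  normal, plus optional divergent units whose loading drifts linearly.
  The planted club partition is returned alongside the panel.

* :func:`simulate_rec_dataset` draws a two-level country-in-grouping
  covariate/outcome panel with planted fixed effects, random-intercept
  variance and residual variance for the determinants stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clubconv.panel import PanelSeries


@dataclass(frozen=True)
class DGPSpec:
    """Parameterization of the loading-process panel simulator.

    ``loadings`` maps each unit to its limiting loading delta_i; units in
    ``divergent`` instead follow delta_it = delta_i + drift * t / T.
    ``slow_var`` selects L(t): ``log1p`` (log(t+1), default — finite at
    t = 1) or ``log`` (log t, with the t = 1 deviation set to theta_i as
    a boundary convention).  ``mu`` is either ("linear", growth-rate) or
    ("random_walk", drift, sd).
    """

    n_periods: int
    loadings: dict[str, float]
    theta: float | dict[str, float] = 0.05
    a: float = 0.5
    slow_var: str = "log1p"
    mu: tuple = ("linear", 0.02)
    divergent: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if len(self.loadings) < 2:
            raise ValueError("need at least 2 units")
        if self.n_periods < 7:
            raise ValueError("need at least 7 periods")
        thetas = self.theta.values() if isinstance(self.theta, dict) else [self.theta]
        if any(th < 0 for th in thetas):
            raise ValueError("theta must be non-negative")
        unknown = set(self.divergent) - set(self.loadings)
        if unknown:
            raise ValueError(f"divergent units not in loadings: {sorted(unknown)}")

    @property
    def units(self) -> tuple[str, ...]:
        return tuple(self.loadings)

    def theta_of(self, unit: str) -> float:
        if isinstance(self.theta, dict):
            return self.theta[unit]
        return self.theta

    def planted_partition(self) -> tuple[list[list[str]], list[str]]:
        """Ground-truth clubs (grouped by limiting loading, highest first)
        and divergent units."""
        non_div = [u for u in self.units if u not in self.divergent]
        by_delta: dict[float, list[str]] = {}
        for u in non_div:
            by_delta.setdefault(self.loadings[u], []).append(u)
        clubs = [by_delta[d] for d in sorted(by_delta, reverse=True)]
        return clubs, list(self.divergent)


def club_dgp(deltas=(1.0, 2.0, 4.0), sizes=(5, 5, 5), n_periods=40,
             theta=0.05, a=0.75, seed=0, n_divergent=0,
             divergent_drift=1.0, **kwargs) -> DGPSpec:
    """Convenience constructor for a planted multi-club DGPSpec.

    Units are named ``c<club>_u<j>`` and divergent units ``div<j>``; the
    divergent loading starts at the panel mean delta and drifts by
    ``divergent_drift`` over the sample.
    """
    loadings: dict[str, float] = {}
    for k, (d, s) in enumerate(zip(deltas, sizes), start=1):
        for j in range(s):
            loadings[f"c{k}_u{j}"] = float(d)
    divergent: dict[str, float] = {}
    base = float(np.mean(deltas))
    for j in range(n_divergent):
        loadings[f"div{j}"] = base
        divergent[f"div{j}"] = divergent_drift * (1 + j)
    return DGPSpec(n_periods=n_periods, loadings=loadings, theta=theta, a=a,
                   seed=seed, divergent=divergent, **kwargs)


def _common_factor(spec: DGPSpec, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(1, spec.n_periods + 1, dtype=float)
    kind = spec.mu[0]
    if kind == "linear":
        growth = spec.mu[1] if len(spec.mu) > 1 else 0.02
        return 1.0 + growth * t
    if kind == "random_walk":
        drift = spec.mu[1] if len(spec.mu) > 1 else 0.02
        sd = spec.mu[2] if len(spec.mu) > 2 else 0.01
        steps = drift + sd * rng.standard_normal(spec.n_periods)
        return 1.0 + np.cumsum(steps)
    raise ValueError(f"unknown common-factor kind {kind!r}")


def simulate_panel(spec: DGPSpec, check_positive: bool = True
                   ) -> tuple[PanelSeries, dict]:
    """Draw a panel from the loading process; returns (panel, ground truth).

    Ground truth carries the planted clubs (ordered by limiting loading,
    highest first), divergent units, and the spec parameters needed by
    recovery oracles.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.n_periods
    t = np.arange(1, T + 1, dtype=float)
    if spec.slow_var == "log1p":
        decay = np.log(t + 1.0) * t ** spec.a
    elif spec.slow_var == "log":
        decay = np.log(t) * t ** spec.a
        decay[0] = 1.0  # L(1) = 0: convention, full-scale deviation at t=1
    else:
        raise ValueError(f"unknown slow_var {spec.slow_var!r}")
    mu = _common_factor(spec, rng)
    units = spec.units
    shocks = rng.standard_normal((len(units), T))
    delta = np.empty((len(units), T))
    for i, u in enumerate(units):
        base = spec.loadings[u]
        if u in spec.divergent:
            path = base + spec.divergent[u] * t / T
        else:
            path = base
        delta[i] = path + spec.theta_of(u) * shocks[i] / decay
    values = delta * mu
    if check_positive and np.any(values <= 0):
        raise ValueError(
            "simulated panel crossed zero; lower theta, raise the loadings, "
            "or pass check_positive=False"
        )
    panel = PanelSeries(units=units, values=values,
                        value_scale="raw" if np.all(values > 0) else "log")
    clubs, divergent = spec.planted_partition()
    truth = {
        "clubs": clubs,
        "divergent": divergent,
        "a": spec.a,
        "loadings": dict(spec.loadings),
        "seed": spec.seed,
    }
    return panel, truth


@dataclass(frozen=True)
class RECDatasetSpec:
    """Parameterization of the two-level covariate/outcome generator.

    Outcome for row (unit i, grouping j, time t):
        y = intercept + x @ beta + u_j + eps,
    u_j ~ N(0, sigma_u^2) per grouping, eps ~ N(0, sigma_e^2) per row.
    Covariates are independent log-normal (log-scale mean 0, sd 1) so the
    determinants stage can log-transform them as the pipeline expects.
    """

    n_groups: int = 8
    units_per_group: int = 5
    n_periods: int = 20
    beta: tuple[float, ...] = (0.5, -0.3, 0.2)
    intercept: float = 1.0
    sigma_u: float = 1.0
    sigma_e: float = 0.5
    covariate_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 2:
            raise ValueError("need at least 2 groupings")
        if self.sigma_u < 0 or self.sigma_e < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def icc(self) -> float:
        denom = self.sigma_u ** 2 + self.sigma_e ** 2
        return self.sigma_u ** 2 / denom if denom > 0 else 0.0


def simulate_rec_dataset(spec: RECDatasetSpec) -> tuple[pd.DataFrame, dict]:
    """Draw the long country-in-grouping table; returns (frame, ground truth).

    Frame columns: grouping, unit, year, y, x1..xp (covariates on the log
    scale, i.e. already suitable as regressors).
    """
    rng = np.random.default_rng(spec.seed)
    p = len(spec.beta)
    beta = np.asarray(spec.beta, dtype=float)
    rows_per_group = spec.units_per_group * spec.n_periods
    n_rows = spec.n_groups * rows_per_group
    u = spec.sigma_u * rng.standard_normal(spec.n_groups)
    x_log = spec.covariate_log_sd * rng.standard_normal((n_rows, p))
    eps = spec.sigma_e * rng.standard_normal(n_rows)
    y = spec.intercept + x_log @ beta + np.repeat(u, rows_per_group) + eps
    groups = np.repeat([f"G{j + 1}" for j in range(spec.n_groups)], rows_per_group)
    units = np.repeat(
        [f"G{j + 1}_U{i + 1}" for j in range(spec.n_groups)
         for i in range(spec.units_per_group)],
        spec.n_periods,
    )
    years = np.tile(np.arange(2000, 2000 + spec.n_periods), n_rows // spec.n_periods)
    frame = pd.DataFrame({"grouping": groups, "unit": units, "year": years, "y": y})
    for k in range(p):
        frame[f"x{k + 1}"] = x_log[:, k]
    truth = {
        "beta": beta.tolist(),
        "intercept": spec.intercept,
        "sigma_u2": spec.sigma_u ** 2,
        "sigma_e2": spec.sigma_e ** 2,
        "icc": spec.icc,
        "group_effects": {f"G{j + 1}": float(u[j]) for j in range(spec.n_groups)},
        "seed": spec.seed,
    }
    return frame, truth
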