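"""Monte-Carlo validation studies for the log-t machinery.

Reusable replication drivers behind the ``study`` CLI subcommand and the
acceptance checks: rejection frequency under convergent (size) and
divergent (power) processes, slope consistency (mean gamma-hat against
2a), and planted-club recovery rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from clubconv.clubs import cluster
from clubconv.logt import logt_regression
from clubconv.simulate import DGPSpec, club_dgp, simulate_panel


def _mc_se(p_hat: float, n: int) -> float:
    return float(np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n))


def convergent_spec(seed: int, a: float = 0.5, n_units: int = 20,
                    n_periods: int = 100, theta: float = 0.05) -> DGPSpec:
    """Common-loading convergent process (null holds)."""
    return DGPSpec(
        n_periods=n_periods,
        loadings={f"u{i}": 1.0 for i in range(n_units)},
        theta=theta, a=a, seed=seed,
    )


def divergent_spec(seed: int, n_units: int = 20, n_periods: int = 100,
                   theta: float = 0.02) -> DGPSpec:
    """Two-level process with no decay toward a common loading.

    Half the units load on 1, half on 2, with permanent idiosyncratic
    noise (a = 0 and L(t) frozen at 1 via theta applied undecayed is
    approximated by a = 0, slow_var log1p at t=1 scale); the panel
    diverges and the log-t test should reject.
    """
    loadings = {f"u{i}": (1.0 if i < n_units // 2 else 2.0)
                for i in range(n_units)}
    return DGPSpec(n_periods=n_periods, loadings=loadings, theta=theta,
                   a=0.0, seed=seed)


def rejection_rate(spec_factory, reps: int, seed: int, critical: float = -1.65
                   ) -> tuple[float, float]:
    """Fraction of replicates with t_gamma < critical, with its MC SE."""
    rng = np.random.default_rng(seed)
    rejected = 0
    for _ in range(reps):
        spec = spec_factory(int(rng.integers(2**31)))
        panel, _ = simulate_panel(spec, check_positive=False)
        res = logt_regression(panel, critical=critical)
        rejected += res.t_gamma < critical
    rate = rejected / reps
    return rate, _mc_se(rate, reps)


def slope_consistency(a_values=(0.25, 0.5, 1.0), reps: int = 200, seed: int = 0,
                      n_units: int = 20, n_periods: int = 100,
                      theta: float = 0.05) -> pd.DataFrame:
    """Mean gamma-hat per decay speed a against the theoretical 2a."""
    rng = np.random.default_rng(seed)
    rows = []
    for a in a_values:
        gammas = np.empty(reps)
        for k in range(reps):
            spec = convergent_spec(int(rng.integers(2**31)), a=a,
                                   n_units=n_units, n_periods=n_periods,
                                   theta=theta)
            panel, _ = simulate_panel(spec, check_positive=False)
            gammas[k] = logt_regression(panel).gamma_hat
        rows.append({
            "a": a,
            "target_gamma": 2 * a,
            "mean_gamma": float(gammas.mean()),
            "sd_gamma": float(gammas.std(ddof=1)),
            "mc_se": float(gammas.std(ddof=1) / np.sqrt(reps)),
            "reps": reps,
        })
    return pd.DataFrame(rows)


def recovery_rate(reps: int = 200, seed: int = 0, deltas=(1.0, 2.0, 4.0),
                  sizes=(5, 5, 5), n_periods: int = 40, theta: float = 0.05,
                  a: float = 0.75, merge: bool = False) -> tuple[float, float]:
    """Fraction of replicates recovering the planted partition exactly."""
    from clubconv.clubs import merge_clubs

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        spec = club_dgp(deltas=deltas, sizes=sizes, n_periods=n_periods,
                        theta=theta, a=a, seed=int(rng.integers(2**31)))
        panel, truth = simulate_panel(spec, check_positive=False)
        part = cluster(panel)
        if merge:
            part = merge_clubs(panel, part)
        got = [sorted(c.members) for c in part.clubs]
        want = [sorted(c) for c in truth["clubs"]]
        hits += got == want and not part.divergent
    rate = hits / reps
    return rate, _mc_se(rate, reps)


def run_study(kind: str, reps: int = 200, seed: int = 0) -> pd.DataFrame:
    """Dispatch for the CLI: one tidy table per study kind."""
    if kind == "size":
        rate, se = rejection_rate(convergent_spec, reps, seed)
        return pd.DataFrame([{"study": "size", "rejection_rate": rate,
                              "mc_se": se, "reps": reps}])
    if kind == "power":
        rate, se = rejection_rate(divergent_spec, reps, seed)
        return pd.DataFrame([{"study": "power", "rejection_rate": rate,
                              "mc_se": se, "reps": reps}])
    if kind == "slope":
        return slope_consistency(reps=reps, seed=seed)
    if kind == "recovery":
        rate, se = recovery_rate(reps=reps, seed=seed)
        return pd.DataFrame([{"study": "recovery", "recovery_rate": rate,
                              "mc_se": se, "reps": reps}])
    raise ValueError(f"unknown study kind {kind!r}")
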