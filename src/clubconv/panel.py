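"""Balanced-panel containers and long-format CSV I/O.

A :class:`PanelSeries` is the object all convergence math consumes: a
balanced N x T matrix of finite values with an internal 1..T time index
(calendar years are metadata only).  A :class:`Membership` maps each
unit to exactly one regional grouping for the inequality/determinants
stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class PanelError(ValueError):
    """Invalid panel input (unbalanced, non-numeric, domain violation)."""


@dataclass(frozen=True)
class PanelSeries:
    """Balanced units-by-time panel.

    Parameters
    ----------
    units : list of str
        Ordered unit identifiers, N >= 2.
    values : ndarray, shape (N, T)
        Finite values; strictly positive when ``value_scale == "raw"``.
    years : list of int, optional
        Calendar-year labels for the T columns; the analysis itself
        always uses the integer index 1..T.
    value_scale : {"raw", "log"}
    """

    units: tuple[str, ...]
    values: np.ndarray
    years: tuple[int, ...] | None = None
    value_scale: str = "raw"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "units", tuple(str(u) for u in self.units))
        if self.years is not None:
            object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        if vals.ndim != 2:
            raise PanelError("values must be a 2-d (units x time) array")
        n, t = vals.shape
        if n < 2:
            raise PanelError(f"need at least 2 units, got {n}")
        if t < 2:
            raise PanelError(f"need at least 2 time periods, got {t}")
        if len(self.units) != n:
            raise PanelError("unit labels do not match the number of rows")
        if len(set(self.units)) != n:
            raise PanelError("duplicate unit identifiers")
        if self.years is not None and len(self.years) != t:
            raise PanelError("year labels do not match the number of columns")
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))
            cells = [(self.units[i], self._label(j)) for i, j in bad[:10]]
            raise PanelError(f"non-finite entries at {cells}")
        if self.value_scale not in ("raw", "log"):
            raise PanelError(f"unknown value_scale {self.value_scale!r}")
        if self.value_scale == "raw" and np.any(vals <= 0):
            bad = np.argwhere(vals <= 0)
            cells = [(self.units[i], self._label(j)) for i, j in bad[:10]]
            raise PanelError(
                f"raw panel has non-positive entries at {cells}; "
                "log transform would be undefined"
            )

    def _label(self, j: int):
        return self.years[j] if self.years is not None else j + 1

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_periods(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Internal 1-based consecutive time index."""
        return np.arange(1, self.n_periods + 1)

    def subset(self, units) -> "PanelSeries":
        """Sub-panel restricted to ``units``, preserving their given order."""
        idx = [self.units.index(str(u)) for u in units]
        return replace(self, units=tuple(self.units[i] for i in idx),
                       values=self.values[idx])

    def to_long(self, id_col="unit", time_col="year", value_col="value") -> pd.DataFrame:
        times = self.years if self.years is not None else self.times
        rows = [
            {id_col: u, time_col: int(t), value_col: self.values[i, j]}
            for i, u in enumerate(self.units)
            for j, t in enumerate(times)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Membership:
    """Unit -> primary grouping mapping with a named roster."""

    mapping: dict[str, str]

    def __post_init__(self):
        object.__setattr__(
            self, "mapping", {str(k): str(v) for k, v in self.mapping.items()}
        )

    @property
    def groupings(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return tuple(seen)

    def members(self, grouping: str) -> tuple[str, ...]:
        return tuple(u for u, g in self.mapping.items() if g == grouping)

    def grouping_of(self, unit: str) -> str:
        try:
            return self.mapping[str(unit)]
        except KeyError:
            raise PanelError(f"unit {unit!r} has no grouping assignment") from None

    def validate_for(self, units, min_members: int = 1) -> None:
        missing = [u for u in units if u not in self.mapping]
        if missing:
            raise PanelError(f"units without grouping assignment: {missing}")
        if min_members > 1:
            counts: dict[str, int] = {}
            for u in units:
                g = self.mapping[u]
                counts[g] = counts.get(g, 0) + 1
            small = [g for g, c in counts.items() if c < min_members]
            if small:
                raise PanelError(
                    f"groupings with fewer than {min_members} members: {small}"
                )


@dataclass
class BalanceReport:
    """What :func:`balance` did: units dropped, cells imputed."""

    dropped_units: list[str] = field(default_factory=list)
    imputed_cells: list[tuple[str, int]] = field(default_factory=list)


def _read_long(path, id_col, time_col, value_col) -> pd.DataFrame:
    # round_trip parser: numeric payload must survive write/read exactly
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (id_col, time_col, value_col):
        if col not in df.columns:
            raise PanelError(f"column {col!r} not found in {path}")
    dup = df.duplicated(subset=[id_col, time_col])
    if dup.any():
        pairs = df.loc[dup, [id_col, time_col]].values.tolist()[:10]
        raise PanelError(f"duplicate (unit, time) pairs: {pairs}")
    vals = pd.to_numeric(df[value_col], errors="coerce")
    bad = vals.isna() & df[value_col].notna()
    if bad.any():
        rows = df.loc[bad, [id_col, time_col, value_col]].values.tolist()[:10]
        raise PanelError(f"non-numeric values at rows {rows}")
    out = df[[id_col, time_col]].copy()
    out.columns = ["unit", "time"]
    out["value"] = vals
    out["unit"] = out["unit"].astype(str)
    out["time"] = out["time"].astype(int)
    return out


def read_panel(path, id_col="unit", time_col="year", value_col="value",
               value_scale="raw") -> PanelSeries:
    """Read a long-format CSV into a balanced :class:`PanelSeries`.

    The calendar times found in ``time_col`` are sorted and mapped to the
    internal index 1..T; a gap for any unit is a hard error listing the
    missing (unit, time) cells — use :func:`balance` for unbalanced input.
    """
    df = _read_long(path, id_col, time_col, value_col)
    return from_long(df, value_scale=value_scale)


def from_long(df: pd.DataFrame, value_scale="raw") -> PanelSeries:
    """Build a PanelSeries from a ``unit,time,value`` frame (must be balanced)."""
    wide = df.pivot(index="unit", columns="time", values="value").sort_index()
    wide = wide[sorted(wide.columns)]
    na = wide.isna()
    if na.any().any():
        missing = [(u, int(t)) for u in na.index for t in na.columns
                   if na.loc[u, t]]
        raise PanelError(f"unbalanced panel; missing cells: {missing[:20]}")
    return PanelSeries(
        units=tuple(wide.index),
        values=wide.to_numpy(),
        years=tuple(int(c) for c in wide.columns),
        value_scale=value_scale,
    )


def write_panel(p: PanelSeries, path, id_col="unit", time_col="year",
                value_col="value") -> None:
    """Write a PanelSeries as the long CSV dialect ``read_panel`` accepts.

    Floats are written with 17 significant digits so the numeric payload
    round-trips bit-identically through ``read_panel``.
    """
    p.to_long(id_col, time_col, value_col).to_csv(path, index=False,
                                                  float_format="%.17g")


def read_membership(path, unit_col="unit", grouping_col="grouping") -> Membership:
    df = pd.read_csv(path)
    for col in (unit_col, grouping_col):
        if col not in df.columns:
            raise PanelError(f"column {col!r} not found in {path}")
    if df[unit_col].duplicated().any():
        dups = df.loc[df[unit_col].duplicated(), unit_col].tolist()
        raise PanelError(f"units with more than one grouping: {dups}")
    return Membership(dict(zip(df[unit_col].astype(str), df[grouping_col].astype(str))))


def log_transform(p: PanelSeries, offset: float | None = None) -> PanelSeries:
    """Entrywise natural log of a raw-scale panel.

    Non-positive entries are a hard error unless an explicit ``offset``
    epsilon is given, in which case log(x + offset) is applied (and
    logged); silent offsets would corrupt cross-unit comparability.
    """
    if p.value_scale != "raw":
        raise PanelError("panel is already on the log scale")
    vals = p.values
    if offset is not None:
        if offset <= 0:
            raise PanelError("log offset must be positive")
        log.info("applying log(x + %g) offset transform", offset)
        vals = vals + offset
    if np.any(vals <= 0):
        bad = np.argwhere(vals <= 0)
        cells = [(p.units[i], p._label(j)) for i, j in bad[:10]]
        raise PanelError(
            f"cannot log-transform non-positive entries at {cells}; "
            "pass an explicit offset to apply log(x + eps)"
        )
    return replace(p, values=np.log(vals), value_scale="log")


def balance(df: pd.DataFrame, policy="drop_units_with_gaps", max_gap=2,
            id_col="unit", time_col="year", value_col="value",
            value_scale="raw") -> tuple[PanelSeries, BalanceReport]:
    """Balance long records into a PanelSeries under an explicit policy.

    ``drop_units_with_gaps`` (default) removes any unit not observed at
    every time; ``interpolate_gaps_up_to_k`` linearly fills interior gap
    runs of length <= ``max_gap`` and drops units with longer or edge
    gaps.  Every drop and imputation is reported and logged.
    """
    if policy not in ("drop_units_with_gaps", "interpolate_gaps_up_to_k"):
        raise PanelError(f"unknown balancing policy {policy!r}")
    if not {id_col, time_col, value_col} <= set(df.columns):
        df = df.rename(columns={"unit": id_col, "time": time_col, "value": value_col})
    longf = df[[id_col, time_col, value_col]].copy()
    longf.columns = ["unit", "time", "value"]
    longf["unit"] = longf["unit"].astype(str)
    longf["time"] = longf["time"].astype(int)
    if longf.duplicated(subset=["unit", "time"]).any():
        raise PanelError("duplicate (unit, time) pairs")
    times = sorted(longf["time"].unique())
    wide = longf.pivot(index="unit", columns="time", values="value")[times]
    report = BalanceReport()
    keep = []
    for unit, row in wide.iterrows():
        isna = row.isna().to_numpy()
        if not isna.any():
            keep.append(unit)
            continue
        if policy == "drop_units_with_gaps":
            report.dropped_units.append(unit)
            continue
        # interior runs only: leading/trailing gaps cannot be interpolated
        first, last = np.flatnonzero(~isna)[[0, -1]] if (~isna).any() else (0, -1)
        interior = isna.copy()
        interior[: first] = False
        interior[last:] = False
        edge_gap = isna[:first].any() or isna[last:].any()
        runs = _run_lengths(interior)
        if edge_gap or (runs and max(runs) > max_gap):
            report.dropped_units.append(unit)
            continue
        filled = row.interpolate(method="linear", limit_area="inside")
        for t in row.index[row.isna()]:
            report.imputed_cells.append((unit, int(t)))
        wide.loc[unit] = filled
        keep.append(unit)
    for u in report.dropped_units:
        log.info("balance: dropped unit %s", u)
    for u, t in report.imputed_cells:
        log.info("balance: imputed (%s, %s)", u, t)
    if len(keep) < 2:
        raise PanelError("fewer than 2 units survive balancing")
    wide = wide.loc[sorted(keep)]
    panel = PanelSeries(
        units=tuple(wide.index),
        values=wide.to_numpy(),
        years=tuple(int(t) for t in wide.columns),
        value_scale=value_scale,
    )
    return panel, report


def _run_lengths(mask: np.ndarray) -> list[int]:
    runs, count = [], 0
    for m in mask:
        if m:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs
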