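"""Gini coefficients within regional groupings per year.

The Gini is the relative mean absolute difference
G = sum_ij |x_i - x_j| / (2 n^2 xbar), without small-sample correction
by default (a bias-corrected n/(n-1) variant is available).  The
grouping-by-year Gini panel is the dependent variable of the
determinants stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from clubconv.panel import Membership, PanelSeries

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GiniPanel:
    """Grouping x year Gini values with member counts.

    Cells for groupings with fewer than 2 members are NaN and listed in
    ``excluded``.
    """

    table: pd.DataFrame          # groupings x years, values in [0, 1)
    counts: pd.Series            # members per grouping
    excluded: tuple[str, ...]    # groupings with < 2 members

    def to_frame(self) -> pd.DataFrame:
        out = self.table.stack().rename("gini").reset_index()
        out.columns = ["grouping", "year", "gini"]
        out["n_members"] = out["grouping"].map(self.counts)
        return out


def gini(values, bias_corrected: bool = False) -> float:
    """Gini coefficient of a non-negative vector (n >= 2).

    All-zero input (mean zero) and negative values are errors.  Computed
    via the sorted-rank identity, which equals the pairwise mean absolute
    difference formula.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector with at least 2 values")
    if np.any(x < 0):
        raise ValueError("Gini is undefined for negative values")
    if not np.any(x > 0):
        raise ValueError("Gini is undefined when all values are zero (mean zero)")
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    g = (2.0 * np.sum(i * xs) / (n * xs.sum())) - (n + 1.0) / n
    if bias_corrected:
        g *= n / (n - 1.0)
    # guard against -eps from cancellation on near-equal inputs
    return float(max(g, 0.0))


def rec_gini_panel(p: PanelSeries, m: Membership, bias_corrected: bool = False
                   ) -> tuple[GiniPanel, pd.DataFrame]:
    """Per grouping-year Gini over member values.

    Returns the GiniPanel plus the country-level long table in which each
    country-year row carries its grouping's Gini (the outcome layout for
    the multilevel model).  Groupings with < 2 members are excluded and
    logged.
    """
    if p.value_scale == "log":
        log.warning(
            "computing Gini on log-scale values; the Gini of logs is "
            "nonstandard — pass the raw indicator if possible"
        )
    m.validate_for(p.units)
    years = list(p.years) if p.years is not None else list(p.times)
    groupings = [g for g in m.groupings if any(u in p.units for u in m.members(g))]
    counts = {g: sum(u in p.units for u in m.members(g)) for g in groupings}
    excluded = tuple(g for g in groupings if counts[g] < 2)
    for g in excluded:
        log.info("grouping %s has < 2 members; Gini undefined, excluded", g)
    table = pd.DataFrame(index=pd.Index(groupings, name="grouping"),
                         columns=pd.Index(years, name="year"), dtype=float)
    for g in groupings:
        if g in excluded:
            continue
        idx = [p.units.index(u) for u in m.members(g) if u in p.units]
        for j, year in enumerate(years):
            table.loc[g, year] = gini(p.values[idx, j], bias_corrected=bias_corrected)
    panel = GiniPanel(table=table, counts=pd.Series(counts), excluded=excluded)
    rows = []
    for i, u in enumerate(p.units):
        g = m.grouping_of(u)
        if g in excluded:
            continue
        for j, year in enumerate(years):
            rows.append({
                "unit": u,
                "grouping": g,
                "year": year,
                "value": p.values[i, j],
                "gini": table.loc[g, year],
            })
    return panel, pd.DataFrame(rows)
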