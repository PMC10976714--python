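"""Core-group club clustering and adjacent-club merging.

The clustering proceeds in four steps: (1) order units by their last
observation, descending; (2) scan down the ordering for the core group
that maximises the log-t t-statistic subject to every leading subgroup
passing the criterion; (3) sieve the remaining units one at a time into
the core; (4) recurse on the unassigned remainder.  A final pass tests
adjacent clubs for merging, restarting after each accepted merge so
chains of fragments collapse deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from clubconv.logt import (
    DEFAULT_CRITICAL,
    DEFAULT_TRIM,
    DegeneratePanelError,
    LogtResult,
    logt_regression,
    logt_report,
)
from clubconv.panel import PanelSeries

log = logging.getLogger(__name__)

# raising schedule for the post-sieve fallback when the extended club
# fails the joint test (the criterion is tightened until it passes)
_SIEVE_RAISE_STEP = 0.5
_SIEVE_RAISE_MAX = 6.0


@dataclass(frozen=True)
class Club:
    members: tuple[str, ...]
    result: LogtResult | None = None  # None for singleton clubs


@dataclass(frozen=True)
class ClubPartition:
    """Ordered clubs plus the divergent remainder at a named stage."""

    clubs: tuple[Club, ...]
    divergent: tuple[str, ...]
    stage: str  # {"initial", "merged", "final"}
    divergent_result: LogtResult | None = None

    def __post_init__(self):
        all_units = [u for c in self.clubs for u in c.members] + list(self.divergent)
        if len(all_units) != len(set(all_units)):
            raise ValueError("clubs and divergent set are not disjoint")

    @property
    def all_units(self) -> tuple[str, ...]:
        return tuple(u for c in self.clubs for u in c.members) + self.divergent

    def to_records(self) -> list[dict]:
        rows = []
        for k, club in enumerate(self.clubs, start=1):
            rec = {"club": f"Club {k}", "n": len(club.members),
                   "members": " | ".join(club.members)}
            if club.result is not None:
                rec.update(logt_report(club.result))
                rec.pop("label")
            rows.append(rec)
        if self.divergent:
            rec = {"club": "Divergent", "n": len(self.divergent),
                   "members": " | ".join(self.divergent)}
            if self.divergent_result is not None:
                rec.update(logt_report(self.divergent_result))
                rec.pop("label")
            rows.append(rec)
        return rows

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "clubs": [
                {
                    "members": list(c.members),
                    "logt": c.result.to_dict() if c.result else None,
                }
                for c in self.clubs
            ],
            "divergent": list(self.divergent),
            "divergent_logt": (
                self.divergent_result.to_dict() if self.divergent_result else None
            ),
        }


def order_units(p: PanelSeries, rule: str = "last_obs") -> list[str]:
    """Step-1 ordering: by last observation descending, stable tie-break
    on the unit identifier.  ``mean_last_half`` orders by the mean over
    the second half of the sample instead."""
    if rule == "last_obs":
        key = p.values[:, -1]
    elif rule == "mean_last_half":
        half = p.n_periods // 2
        key = p.values[:, half:].mean(axis=1)
    else:
        raise ValueError(f"unknown ordering rule {rule!r}")
    order = sorted(range(p.n_units), key=lambda i: (-key[i], p.units[i]))
    return [p.units[i] for i in order]


def _t_stat(p: PanelSeries, members, r, hac_lags, critical) -> float:
    """log-t t-statistic of a subgroup, with degenerate panels resolved:
    units identical on the window converge trivially (+inf); units that
    coincide only at t=1 and then spread count as divergent (-inf)."""
    try:
        res = logt_regression(p.subset(members), r=r, hac_lags=hac_lags,
                              critical=critical)
    except DegeneratePanelError as exc:
        return float(np.inf) if exc.where == "window" else float(-np.inf)
    return res.t_gamma


def form_core(p: PanelSeries, ordering=None, critical: float = DEFAULT_CRITICAL,
              r: float = DEFAULT_TRIM, hac_lags: int | None = None) -> list[str]:
    """Step-2 core group: the leading run of ordered units whose log-t
    t-statistic stays above the criterion, sized to maximise it.

    If even the top pair fails, the top unit is set aside and the scan
    restarts from the next unit; an empty list means no pair anywhere
    qualifies.
    """
    if ordering is None:
        ordering = order_units(p)
    n = len(ordering)
    for j in range(n - 1):
        best_R, best_t = None, -np.inf
        for R in range(2, n - j + 1):
            t_g = _t_stat(p, ordering[j:j + R], r, hac_lags, critical)
            if t_g <= critical:
                break  # leading-run criterion: stop at first failure
            if t_g > best_t:
                best_t, best_R = t_g, R
        if best_R is not None:
            core = ordering[j:j + best_R]
            log.info("core group: %s (t=%.3f)", core, best_t)
            return core
        log.info("core search: set aside %s", ordering[j])
    return []


def sieve_members(p: PanelSeries, core, c_star: float = DEFAULT_CRITICAL,
                  ordering=None, r: float = DEFAULT_TRIM,
                  hac_lags: int | None = None,
                  critical: float = DEFAULT_CRITICAL) -> list[str]:
    """Step-3 sieve: each remaining unit is added alone to the core; it
    joins the club when the log-t t-statistic of core + unit exceeds
    ``c_star``.  Returns core plus all accepted units in Step-1 order."""
    if not core:
        raise ValueError("sieve requires a non-empty core group")
    if ordering is None:
        ordering = order_units(p)
    club = list(core)
    for unit in ordering:
        if unit in core:
            continue
        t_g = _t_stat(p, list(core) + [unit], r, hac_lags, critical)
        if t_g > c_star:
            club.append(unit)
            log.info("sieve: %s joins (t=%.3f > %.2f)", unit, t_g, c_star)
        else:
            log.info("sieve: %s rejected (t=%.3f <= %.2f)", unit, t_g, c_star)
    return [u for u in ordering if u in club]


def _form_club(p: PanelSeries, ordering, c_star, critical, r, hac_lags) -> list[str]:
    """Steps 2-3 plus the joint re-test fallback: if the sieved club fails
    the log-t test as a whole, the sieve criterion is raised stepwise
    until the club passes (worst case it shrinks back to the core)."""
    core = form_core(p, ordering, critical=critical, r=r, hac_lags=hac_lags)
    if not core:
        return []
    c = c_star
    while True:
        club = sieve_members(p, core, c_star=c, ordering=ordering, r=r,
                             hac_lags=hac_lags, critical=critical)
        if club == list(core) or _t_stat(p, club, r, hac_lags, critical) > critical:
            return club
        c += _SIEVE_RAISE_STEP
        if c > _SIEVE_RAISE_MAX:
            return list(core)
        log.info("club failed joint re-test; raising sieve criterion to %.2f", c)


def cluster(p: PanelSeries, c_star: float = DEFAULT_CRITICAL,
            critical: float = DEFAULT_CRITICAL, r: float = DEFAULT_TRIM,
            hac_lags: int | None = None,
            ordering_rule: str = "last_obs") -> ClubPartition:
    """Full Step-1..4 clustering into an initial ClubPartition.

    The recursion runs order/core/sieve on the unassigned remainder; a
    remainder that jointly passes the log-t test becomes the last club,
    a singleton remainder (or one with no qualifying pair) goes to the
    divergent set.
    """
    clubs: list[Club] = []
    divergent: list[str] = []
    remaining = list(p.units)
    while remaining:
        if len(remaining) == 1:
            divergent.extend(remaining)
            break
        sub = p.subset(remaining)
        joint_t = _t_stat(p, remaining, r, hac_lags, critical)
        if joint_t > critical:
            members = order_units(sub, rule=ordering_rule)
            clubs.append(Club(tuple(members),
                              _club_result(p, members, r, hac_lags, critical)))
            break
        ordering = order_units(sub, rule=ordering_rule)
        club = _form_club(p, ordering, c_star, critical, r, hac_lags)
        if not club:
            divergent.extend(ordering)
            break
        clubs.append(Club(tuple(club), _club_result(p, club, r, hac_lags, critical)))
        remaining = [u for u in remaining if u not in club]
    part = ClubPartition(
        clubs=tuple(clubs),
        divergent=tuple(divergent),
        stage="initial",
        divergent_result=_divergent_result(p, divergent, r, hac_lags, critical),
    )
    _check_partition(p, part, critical, r, hac_lags)
    return part


def merge_clubs(p: PanelSeries, part: ClubPartition,
                critical: float = DEFAULT_CRITICAL, r: float = DEFAULT_TRIM,
                hac_lags: int | None = None) -> ClubPartition:
    """Adjacent-club merging: test each neighbouring pair with log-t on
    the union; merge on pass and restart the pass, so transitive chains
    of over-split fragments end up in one club.  Idempotent on an
    already-final partition; the divergent set is never touched."""
    clubs = [list(c.members) for c in part.clubs]
    changed = True
    while changed:
        changed = False
        for k in range(len(clubs) - 1):
            union = clubs[k] + clubs[k + 1]
            t_g = _t_stat(p, union, r, hac_lags, critical)
            if t_g > critical:
                log.info("merge: clubs %d+%d accepted (t=%.3f)", k + 1, k + 2, t_g)
                merged = order_units(p.subset(union))
                clubs[k: k + 2] = [merged]
                changed = True
                break
            log.info("merge: clubs %d+%d rejected (t=%.3f)", k + 1, k + 2, t_g)
    final = ClubPartition(
        clubs=tuple(
            Club(tuple(c), _club_result(p, c, r, hac_lags, critical)) for c in clubs
        ),
        divergent=part.divergent,
        stage="final",
        divergent_result=part.divergent_result,
    )
    _check_partition(p, final, critical, r, hac_lags)
    return final


def merge_test_table(p: PanelSeries, part: ClubPartition,
                     critical: float = DEFAULT_CRITICAL, r: float = DEFAULT_TRIM,
                     hac_lags: int | None = None) -> list[dict]:
    """Diagnostic table of the adjacent-pair log-t tests on a partition."""
    rows = []
    for k in range(len(part.clubs) - 1):
        union = list(part.clubs[k].members) + list(part.clubs[k + 1].members)
        try:
            res = logt_regression(p.subset(union), r=r, hac_lags=hac_lags,
                                  critical=critical)
            rec = logt_report(res, label=f"Club {k + 1}+{k + 2}")
        except DegeneratePanelError:
            rec = {"label": f"Club {k + 1}+{k + 2}", "coeff": np.nan,
                   "se": np.nan, "t_stat": np.inf, "converged": True}
        rows.append(rec)
    return rows


def _club_result(p, members, r, hac_lags, critical) -> LogtResult | None:
    if len(members) < 2:
        return None
    try:
        return logt_regression(p.subset(members), r=r, hac_lags=hac_lags,
                               critical=critical)
    except DegeneratePanelError:
        return None


def _divergent_result(p, divergent, r, hac_lags, critical) -> LogtResult | None:
    # diagnostic only: the divergent set is not a club
    if len(divergent) < 2:
        return None
    try:
        return logt_regression(p.subset(divergent), r=r, hac_lags=hac_lags,
                               critical=critical)
    except DegeneratePanelError:
        return None


def _check_partition(p: PanelSeries, part: ClubPartition, critical, r, hac_lags):
    """Structural invariants asserted on every emitted partition."""
    if sorted(part.all_units) != sorted(p.units):
        raise AssertionError("partition does not cover the panel units exactly")
    for k, club in enumerate(part.clubs, start=1):
        if len(club.members) >= 2:
            t_g = _t_stat(p, list(club.members), r, hac_lags, critical)
            if not t_g > critical:
                raise AssertionError(
                    f"club {k} fails the log-t criterion (t={t_g:.3f})"
                )


def relabel(part: ClubPartition, stage: str) -> ClubPartition:
    return replace(part, stage=stage)
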