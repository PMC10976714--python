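import numpy as np
import pytest

from clubconv.clubs import (
    ClubPartition,
    cluster,
    form_core,
    merge_clubs,
    merge_test_table,
    order_units,
    sieve_members,
)
from clubconv.logt import logt_regression
from clubconv.panel import PanelSeries
from clubconv.simulate import club_dgp, simulate_panel


@pytest.fixture(scope="module")
def two_club_panel():
    spec = club_dgp(deltas=(2.0, 1.0), sizes=(5, 5), n_periods=40,
                    theta=0.05, a=0.75, seed=11)
    return simulate_panel(spec)


@pytest.fixture(scope="module")
def three_club_panel():
    spec = club_dgp(deltas=(1.0, 2.0, 4.0), sizes=(5, 5, 5), n_periods=40,
                    theta=0.05, a=0.75, seed=23)
    return simulate_panel(spec)


class TestOrderUnits:
    def test_last_observation_descending(self):
        vals = np.ones((3, 8)) * [[3.0], [1.0], [2.0]]
        p = PanelSeries(units=("A", "B", "C"), values=vals)
        assert order_units(p) == ["A", "C", "B"]

    def test_tie_breaks_on_unit_id(self):
        vals = np.ones((2, 8)) * 2.0
        p = PanelSeries(units=("B", "A"), values=vals)
        assert order_units(p) == ["A", "B"]

    def test_mean_last_half_rule(self):
        # A ends high but averages low over the second half
        a = np.concatenate([np.ones(6), [0.5, 0.5, 0.5, 3.0]])
        b = np.concatenate([np.ones(6), [2.0, 2.0, 2.0, 2.0]])
        p = PanelSeries(units=("A", "B"), values=np.vstack([a, b]))
        assert order_units(p) == ["A", "B"]
        assert order_units(p, rule="mean_last_half") == ["B", "A"]

    def test_unknown_rule(self, small_panel):
        with pytest.raises(ValueError):
            order_units(small_panel, rule="nope")


class TestFormCore:
    def test_core_within_top_club(self, two_club_panel):
        p, truth = two_club_panel
        core = form_core(p)
        top_club = set(truth["clubs"][0])
        assert len(core) >= 2
        assert set(core) <= top_club

    def test_fully_convergent_panel_can_take_all(self):
        spec = club_dgp(deltas=(1.0,), sizes=(8,), n_periods=60, theta=0.02,
                        a=0.75, seed=3)
        p, _ = simulate_panel(spec)
        core = form_core(p)
        assert len(core) >= 2  # monotone case may extend to all units

    def test_mutually_diverging_units_empty_core(self):
        T = 40
        t = np.arange(1, T + 1, dtype=float)
        # distinct growth orders, no ties at t = 1 (H_1 > 0 for every pair)
        vals = np.vstack([np.ones(T), 0.6 * t, 0.3 * t ** 1.5,
                          2.2 * np.exp(0.2 * t)])
        p = PanelSeries(units=("a", "b", "c", "d"), values=vals)
        # oracle: every pair fails the log-t criterion
        from itertools import combinations

        for pair in combinations(p.units, 2):
            assert logt_regression(p.subset(pair)).t_gamma <= -1.65
        assert form_core(p) == []


class TestSieve:
    def test_accepts_rest_of_first_club(self, two_club_panel):
        p, truth = two_club_panel
        core = form_core(p)
        club = sieve_members(p, core)
        assert set(club) == set(truth["clubs"][0])

    def test_plus_infinity_criterion_keeps_core_only(self, two_club_panel):
        p, _ = two_club_panel
        core = form_core(p)
        assert sieve_members(p, core, c_star=np.inf) == sorted(
            core, key=lambda u: order_units(p).index(u))

    def test_minus_infinity_criterion_admits_all(self, two_club_panel):
        p, _ = two_club_panel
        core = form_core(p)
        assert set(sieve_members(p, core, c_star=-np.inf)) == set(p.units)

    def test_empty_core_rejected(self, small_panel):
        with pytest.raises(ValueError):
            sieve_members(small_panel, [])


class TestCluster:
    def test_recovers_planted_three_clubs(self, three_club_panel):
        p, truth = three_club_panel
        part = cluster(p)
        assert part.stage == "initial"
        got = [sorted(c.members) for c in part.clubs]
        assert got == [sorted(c) for c in truth["clubs"]]
        assert part.divergent == ()

    def test_single_convergent_dgp_gives_one_club(self):
        spec = club_dgp(deltas=(1.0,), sizes=(10,), n_periods=60, theta=0.02,
                        a=0.75, seed=5)
        p, _ = simulate_panel(spec)
        part = cluster(p)
        assert len(part.clubs) == 1
        assert set(part.clubs[0].members) == set(p.units)
        assert part.divergent == ()

    def test_planted_divergent_unit_isolated(self):
        spec = club_dgp(deltas=(1.0, 2.0), sizes=(6, 6), n_periods=40,
                        theta=0.04, a=0.75, seed=9, n_divergent=1,
                        divergent_drift=4.0)
        p, truth = simulate_panel(spec)
        part = cluster(p)
        assert set(truth["divergent"]) <= set(part.divergent)

    def test_partition_covers_all_units(self, three_club_panel):
        p, _ = three_club_panel
        part = cluster(p)
        assert sorted(part.all_units) == sorted(p.units)

    def test_every_club_passes_logt_independently(self, three_club_panel):
        p, _ = three_club_panel
        part = cluster(p)
        for club in part.clubs:
            if len(club.members) >= 2:
                assert logt_regression(p.subset(club.members)).t_gamma > -1.65

    def test_permutation_invariance(self, three_club_panel):
        p, _ = three_club_panel
        rng = np.random.default_rng(0)
        perm = rng.permutation(p.n_units)
        shuffled = PanelSeries(units=tuple(p.units[i] for i in perm),
                               values=p.values[perm])
        a = [sorted(c.members) for c in cluster(p).clubs]
        b = [sorted(c.members) for c in cluster(shuffled).clubs]
        assert a == b

    def test_overlapping_clubs_rejected_by_partition_type(self):
        from clubconv.clubs import Club

        with pytest.raises(ValueError, match="disjoint"):
            ClubPartition(clubs=(Club(("a", "b")), Club(("b", "c"))),
                          divergent=(), stage="initial")


class TestMerge:
    def test_split_club_remerges(self):
        spec = club_dgp(deltas=(1.0,), sizes=(10,), n_periods=60, theta=0.02,
                        a=0.75, seed=13)
        p, _ = simulate_panel(spec)
        ordering = order_units(p)
        from clubconv.clubs import Club

        part = ClubPartition(
            clubs=(Club(tuple(ordering[:5])), Club(tuple(ordering[5:]))),
            divergent=(), stage="initial",
        )
        merged = merge_clubs(p, part)
        assert merged.stage == "final"
        assert len(merged.clubs) == 1
        assert set(merged.clubs[0].members) == set(p.units)

    def test_distinct_clubs_do_not_merge(self):
        spec = club_dgp(deltas=(4.0, 1.0), sizes=(5, 5), n_periods=40,
                        theta=0.01, a=0.75, seed=17)
        p, truth = simulate_panel(spec)
        part = cluster(p)
        assert len(part.clubs) == 2
        # oracle: the union fails log-t directly
        union = list(part.clubs[0].members) + list(part.clubs[1].members)
        assert logt_regression(p.subset(union)).t_gamma <= -1.65
        merged = merge_clubs(p, part)
        assert [sorted(c.members) for c in merged.clubs] == \
               [sorted(c.members) for c in part.clubs]

    def test_chain_merge_of_three_fragments(self):
        spec = club_dgp(deltas=(1.0,), sizes=(12,), n_periods=60, theta=0.02,
                        a=0.75, seed=19)
        p, _ = simulate_panel(spec)
        ordering = order_units(p)
        from clubconv.clubs import Club

        part = ClubPartition(
            clubs=(Club(tuple(ordering[:4])), Club(tuple(ordering[4:8])),
                   Club(tuple(ordering[8:]))),
            divergent=(), stage="initial",
        )
        merged = merge_clubs(p, part)
        assert len(merged.clubs) == 1

    def test_idempotent_on_final_partition(self, three_club_panel):
        p, _ = three_club_panel
        final = merge_clubs(p, cluster(p))
        again = merge_clubs(p, final)
        assert [c.members for c in again.clubs] == [c.members for c in final.clubs]
        assert again.divergent == final.divergent

    def test_merge_table_rows(self, three_club_panel):
        p, _ = three_club_panel
        part = cluster(p)
        rows = merge_test_table(p, part)
        assert len(rows) == len(part.clubs) - 1
        assert all("t_stat" in r for r in rows)

    def test_divergent_set_untouched(self):
        spec = club_dgp(deltas=(1.0, 2.0), sizes=(6, 6), n_periods=40,
                        theta=0.04, a=0.75, seed=9, n_divergent=1,
                        divergent_drift=4.0)
        p, _ = simulate_panel(spec)
        part = cluster(p)
        merged = merge_clubs(p, part)
        assert merged.divergent == part.divergent


def test_partition_serialization(three_club_panel):
    import json

    p, _ = three_club_panel
    part = cluster(p)
    payload = json.loads(json.dumps(part.to_dict()))
    assert payload["stage"] == "initial"
    assert len(payload["clubs"]) == 3
    records = part.to_records()
    assert records[0]["club"] == "Club 1"
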