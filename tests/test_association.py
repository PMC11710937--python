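import numpy as np
import pytest

from socioscope import (
    Individual,
    build_harem_network,
    build_harem_networks,
    compare_periods,
    compute_sri,
    cross_period_dyad_regression,
    coefficient_of_variation,
    preferred_associate_test,
    tally_dyads,
)
from socioscope.association import DyadTally
from socioscope.evaluation import edge_shuffle_toy_network

from conftest import make_scans


class TestSRI:
    @pytest.mark.parametrize("counts,expected", [
        ((3, 1, 1, 0), 0.6),
        ((2, 1, 0, 1), 0.5),
        ((0, 2, 3, 1), 0.0),
        ((5, 0, 0, 0), 1.0),
    ])
    def test_formula(self, counts, expected):
        assert compute_sri(*counts) == pytest.approx(expected)

    def test_all_zero_counts_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert compute_sri(0, 0, 0, 0) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_sri(-1, 0, 0, 0)


class TestTally:
    def test_hand_tallied_example(self):
        # a,b in association in 3 periods; one period only a; one only b.
        scans = make_scans({
            "P1": [("a", "b"), ("b", "a")],
            "P2": [("a", "b"), ("b", "a")],
            "P3": [("b", "a"), ("a", "NONE")],   # one-sided naming still counts
            "P4": [("a", "NONE")],
            "P5": [("b", "NONE")],
        })
        (t,) = tally_dyads(scans)
        assert (t.x, t.y_a, t.y_b, t.y_ab) == (3, 1, 1, 0)
        assert t.sri == pytest.approx(0.6)

    def test_never_associated_and_always_associated(self):
        apart = make_scans({"P1": [("a", "NONE"), ("b", "NONE")],
                            "P2": [("a", "NONE"), ("b", "NONE")]})
        (t,) = tally_dyads(apart)
        assert t.sri == 0.0
        together = make_scans({"P1": [("a", "b")], "P2": [("b", "a")]})
        (t,) = tally_dyads(together)
        assert t.sri == 1.0

    def test_counts_partition_joint_observation_periods(self):
        scans = make_scans({
            "P1": [("a", "b"), ("c", "NONE")],
            "P2": [("a", "c"), ("b", "NONE")],
            "P3": [("b", "c")],
            "P4": [("a", "NONE")],
        })
        periods_with = {
            "a": {"P1", "P2", "P4"}, "b": {"P1", "P2", "P3"}, "c": {"P1", "P2", "P3"},
        }
        for t in tally_dyads(scans):
            either = periods_with[t.a_id] | periods_with[t.b_id]
            assert t.x + t.y_a + t.y_b + t.y_ab == len(either)

    def test_empty_scan_set(self):
        assert tally_dyads([]) == []


class TestHaremNetwork:
    def _roster(self, n, harem="H1"):
        return [Individual(x, harem, "nonlactating_female", 60.0)
                for x in "abcdefg"[:n]]

    def test_complete_trio(self):
        scans = make_scans({"P1": [("a", "b"), ("c", "a")],
                            "P2": [("b", "c"), ("a", "b")]})
        net = build_harem_network(tally_dyads(scans), self._roster(3))
        assert net.density == 1.0
        assert all(m["degree"] == 2 for m in net.node_metrics.values())

    def test_half_density(self):
        tallies = [
            DyadTally("a", "b", 1, 0, 0, 1), DyadTally("a", "c", 1, 0, 0, 1),
            DyadTally("a", "d", 1, 0, 0, 1), DyadTally("b", "c", 0, 1, 1, 2),
            DyadTally("b", "d", 0, 1, 1, 2), DyadTally("c", "d", 0, 1, 1, 2),
        ]
        net = build_harem_network(tallies, self._roster(4))
        assert net.density == pytest.approx(0.5)

    def test_equal_sris_give_zero_node_cv(self):
        tallies = [DyadTally(a, b, 1, 0, 0, 4)
                   for a, b in [("a", "b"), ("a", "c"), ("a", "d")]]
        tallies += [DyadTally(a, b, 1, 0, 0, 4)
                    for a, b in [("b", "c"), ("b", "d"), ("c", "d")]]
        net = build_harem_network(tallies, self._roster(4))
        assert net.node_metrics["a"]["cv_sri"] == pytest.approx(0.0)

    def test_juveniles_under_one_year_excluded(self):
        roster = self._roster(3) + [Individual("j", "H1", "juvenile", 6.0)]
        scans = make_scans({"P1": [("a", "j"), ("b", "c")]})
        net = build_harem_network(tally_dyads(scans, roster), roster)
        assert "j" not in net.graph.nodes

    def test_tiny_harem_density_missing(self):
        net = build_harem_network([], [Individual("a", "H1")])
        assert net.density is None


class TestCV:
    def test_two_values(self):
        assert coefficient_of_variation([0.1, 0.3]) == pytest.approx(0.70710678, abs=1e-6)

    def test_constant(self):
        assert coefficient_of_variation([0.2, 0.2, 0.2]) == pytest.approx(0.0, abs=1e-12)

    def test_single_value_missing_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(coefficient_of_variation([0.5]))

    def test_zero_mean_missing_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(coefficient_of_variation([0.0, 0.0]))


class TestPreferredAssociateTest:
    def test_small_harem_refused(self):
        roster = [Individual(x, "H1", age_months=60.0) for x in "abcd"]
        scans = make_scans({"P1": [("a", "b"), ("c", "d")]})
        net = build_harem_network(tally_dyads(scans, roster), roster)
        with pytest.raises(ValueError, match="more than 4"):
            preferred_associate_test(net, scans=scans, n_perm=10, seed=0)

    def test_observed_above_all_nulls_gives_p_zero(self):
        # one extreme dyad, everything else near-zero: the count/n convention
        # can return exactly 0.
        periods = {}
        for t in range(30):
            periods[f"P{t}"] = [("a", "b"), ("c", "NONE"), ("d", "NONE"), ("e", "NONE")]
        periods["P30"] = [("c", "d"), ("a", "NONE"), ("b", "NONE"), ("e", "c")]
        scans = make_scans(periods)
        roster = [Individual(x, "H1", age_months=60.0) for x in "abcde"]
        net = build_harem_network(tally_dyads(scans, roster), roster)
        res = preferred_associate_test(net, scans=scans, n_perm=200, seed=1)
        assert res.p_value == 0.0

    def test_degenerate_equal_weights_give_p_one(self):
        # complete graph with identical weights: every random placement is the
        # same network, CV ties count toward the upper tail, p = 1.
        import networkx as nx
        from socioscope.association import HaremNetwork

        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        nx.set_edge_attributes(g, 0.4, "weight")
        net = HaremNetwork("H", "x", g, {})
        res = preferred_associate_test(net, n_perm=50, seed=0, method="edge_shuffle")
        assert res.observed == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_plus_one_convention_never_zero(self):
        net = edge_shuffle_toy_network()
        res = preferred_associate_test(net, n_perm=50, seed=3,
                                       method="edge_shuffle", convention="plus_one")
        assert res.p_value >= 1 / 51


class TestCrossPeriod:
    def test_identity_regression(self):
        tallies = [DyadTally("a", "b", 2, 1, 1, 0), DyadTally("a", "c", 1, 1, 1, 1),
                   DyadTally("b", "c", 3, 0, 0, 1)]
        res = cross_period_dyad_regression(tallies, tallies)
        assert res["slope"] == pytest.approx(1.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_closed_form_ols_on_four_points(self):
        # late SRIs chosen freely; oracle = normal equations evaluated by hand
        pre = [DyadTally("a", "b", 1, 0, 0, 9), DyadTally("a", "c", 2, 0, 0, 8),
               DyadTally("a", "d", 3, 0, 0, 7), DyadTally("a", "e", 4, 0, 0, 6)]
        late = [DyadTally("a", "b", 2, 0, 0, 8), DyadTally("a", "c", 1, 0, 0, 9),
                DyadTally("a", "d", 5, 0, 0, 5), DyadTally("a", "e", 4, 0, 0, 6)]
        res = cross_period_dyad_regression(pre, late)
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([0.2, 0.1, 0.5, 0.4])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert res["slope"] == pytest.approx(slope)
        assert res["intercept"] == pytest.approx(intercept)

    def test_independent_periods_have_near_zero_r_squared(self):
        rng = np.random.default_rng(7)
        pre = [DyadTally(f"i{k}", f"j{k}", int(rng.integers(0, 10)), 2, 2,
                         int(rng.integers(0, 10))) for k in range(400)]
        late = [DyadTally(f"i{k}", f"j{k}", int(rng.integers(0, 10)), 2, 2,
                          int(rng.integers(0, 10))) for k in range(400)]
        res = cross_period_dyad_regression(pre, late)
        assert res["r_squared"] < 0.02

    def test_too_few_shared_dyads(self):
        t = [DyadTally("a", "b", 1, 0, 0, 1)]
        with pytest.warns(UserWarning):
            assert cross_period_dyad_regression(t, t) is None


class TestComparePeriods:
    def _nets(self, periods, roster):
        scans = make_scans(periods)
        return build_harem_networks(scans, roster)

    def test_identical_networks_zero_deltas(self):
        roster = [Individual(x, "H1", age_months=60.0) for x in "abc"]
        periods = {"P1": [("a", "b"), ("c", "a")], "P2": [("b", "c")]}
        a = self._nets(periods, roster)
        b = self._nets(periods, roster)
        table = compare_periods(a, b)
        assert (table["delta"].abs() < 1e-12).all()

    def test_individual_missing_late_excluded(self):
        roster_pre = [Individual(x, "H1", age_months=60.0) for x in "abc"]
        roster_late = [Individual(x, "H1", age_months=60.0) for x in "ab"]
        a = self._nets({"P1": [("a", "b"), ("c", "a")]}, roster_pre)
        b = self._nets({"P1": [("a", "b")]}, roster_late)
        table = compare_periods(a, b)
        ind = table[table.level == "individual"]
        assert set(ind["unit"]) == {"a", "b"}

    def test_halved_edge_changes_only_that_dyad(self):
        roster = [Individual(x, "H1", age_months=60.0) for x in "abc"]
        pre = {"P1": [("a", "b")], "P2": [("a", "b")],
               "P3": [("b", "c")], "P4": [("b", "c")]}
        late = {"P1": [("a", "b")], "P2": [("a", "NONE"), ("b", "NONE")],
                "P3": [("b", "c")], "P4": [("b", "c")]}
        table = compare_periods(self._nets(pre, roster), self._nets(late, roster))
        dyads = table[table.level == "dyad"].set_index("unit")
        assert dyads.loc["a--b", "delta"] == pytest.approx(-0.25)
        assert dyads.loc["b--c", "delta"] == 0.0
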