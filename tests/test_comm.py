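import networkx as nx
import numpy as np
import pytest

from socioscope import (
    CommNetwork,
    Component,
    Ethogram,
    InteractionRecord,
    Posture,
    adjusted_density,
    build_comm_network,
    clean_postures,
    compare_modules,
    component_diversity,
    density_node_subsample_null,
    detect_modules,
    diversity_jackknife,
    impossible_pairs,
    modality_loss_summary,
    neutral_subgraph,
    postures_of,
)
from socioscope.evaluation import cleaning_fixture


def interactions_from(spec, period="x"):
    return [
        InteractionRecord(iid, period, "F", [Posture(frozenset(p)) for p in ps])
        for iid, ps in spec
    ]


def singleton_ethogram(codes, modality="visual"):
    return Ethogram([Component(c, c, modality) for c in codes])


class TestCleaning:
    def test_single_interaction_component_removed(self):
        inter = interactions_from([
            ("I1", [{"A", "B"}, {"A", "rare"}]),
            ("I2", [{"A", "B"}]),
        ])
        kept, report = clean_postures(inter)
        assert report.postures_removed == 1
        assert "rare" in report.removed_components
        assert all("rare" not in p.components for p in postures_of(kept))

    def test_two_interaction_component_retained(self):
        inter = interactions_from([
            ("I1", [{"A", "B"}]), ("I2", [{"A", "B"}]),
        ])
        kept, report = clean_postures(inter)
        assert report.postures_removed == 0
        assert report.removed_components == {}

    def test_ten_posture_fixture_keeps_seven(self):
        inter, _ = cleaning_fixture()
        kept, report = clean_postures(inter)
        assert report.postures_in == 10
        assert report.postures_out == 7
        assert set(report.removed_components) == {"zz"}

    def test_fixpoint_cascade(self):
        # Y occurs in one interaction; removing its postures drops X below
        # two interactions, so the fixpoint pass must also remove X postures.
        inter = interactions_from([
            ("I1", [{"X", "Y"}, {"A", "B"}]),
            ("I2", [{"X", "A"}, {"A", "B"}]),
            ("I3", [{"A", "B"}]),
        ])
        one_pass, rep1 = clean_postures(inter, to_fixpoint=False)
        assert any("X" in p.components for p in postures_of(one_pass))
        fixpoint, rep2 = clean_postures(inter)
        assert all("X" not in p.components for p in postures_of(fixpoint))
        assert rep2.passes > rep1.passes
        again, rep3 = clean_postures(fixpoint)
        assert rep3.postures_removed == 0  # idempotent at the fixpoint


class TestBuild:
    def test_triangle_from_single_posture(self):
        eth = singleton_ethogram("ABC")
        net = build_comm_network(interactions_from([("I1", [{"A", "B", "C"}])]), eth)
        assert {frozenset(e) for e in net.graph.edges} == {
            frozenset({"A", "B"}), frozenset({"A", "C"}), frozenset({"B", "C"})}
        assert all(d["weight"] == 1 for _, _, d in net.graph.edges(data=True))

    def test_repeated_posture_accumulates_weight(self):
        eth = singleton_ethogram("AB")
        net = build_comm_network(
            interactions_from([("I1", [{"A", "B"}, {"A", "B"}])]), eth)
        assert net.graph["A"]["B"]["weight"] == 2

    def test_six_posture_fixture_matches_hand_tally(self):
        eth = singleton_ethogram("ABCD")
        postures = [{"A", "B"}, {"A", "B", "C"}, {"C", "D"},
                    {"A", "C"}, {"B", "D"}, {"A", "B"}]
        net = build_comm_network(interactions_from([("I1", postures)]), eth)
        expected = {("A", "B"): 3, ("A", "C"): 2, ("B", "C"): 1,
                    ("C", "D"): 1, ("B", "D"): 1}
        got = {tuple(sorted(e)): d["weight"] for *e, d in net.graph.edges(data=True)}
        assert got == expected

    def test_interaction_unit_weighting(self):
        eth = singleton_ethogram("AB")
        inter = interactions_from([("I1", [{"A", "B"}, {"A", "B"}]),
                                   ("I2", [{"A", "B"}])])
        net = build_comm_network(inter, eth, unit="interaction")
        assert net.graph["A"]["B"]["weight"] == 2


class TestNeutralSubgraph:
    def _net_with_neutral(self, n_neutral):
        comps = [Component(f"s{i}", f"s{i}") for i in range(6 - n_neutral)]
        comps += [Component(f"n{i}", f"n{i}", neutral=True) for i in range(n_neutral)]
        eth = Ethogram(comps)
        codes = [c.code for c in comps]
        inter = interactions_from([("I1", [set(codes[:3]), set(codes[3:])])])
        return build_comm_network(inter, eth), eth

    def test_neutral_nodes_removed(self):
        net, eth = self._net_with_neutral(2)
        sub = neutral_subgraph(net, eth)
        assert sub.graph.number_of_nodes() == 4
        assert not set(sub.graph.nodes) & eth.neutral_codes

    def test_all_neutral_gives_empty_graph(self):
        net, eth = self._net_with_neutral(6)
        assert neutral_subgraph(net, eth).graph.number_of_nodes() == 0

    def test_empty_neutral_set_warns_identity(self):
        eth = singleton_ethogram("AB")
        net = build_comm_network(interactions_from([("I1", [{"A", "B"}])]), eth)
        with pytest.warns(UserWarning):
            sub = neutral_subgraph(net, eth)
        assert set(sub.graph.nodes) == {"A", "B"}

    def test_disconnection_preserved_without_recleaning(self):
        # removing the neutral hub disconnects A-B from C-D; weights persist
        comps = [Component(c, c) for c in "ABCD"] + [Component("hub", "hub", neutral=True)]
        eth = Ethogram(comps)
        inter = interactions_from([
            ("I1", [{"A", "hub"}, {"A", "B"}]),
            ("I2", [{"C", "hub"}, {"C", "D"}, {"A", "B"}, {"C", "D"}]),
        ])
        net = build_comm_network(inter, eth)
        sub = neutral_subgraph(net, eth)
        assert nx.number_connected_components(sub.graph) == 2
        assert sub.graph["C"]["D"]["weight"] == 2


class TestDiversityAndDensity:
    def test_isolated_nodes_not_counted(self):
        eth = singleton_ethogram("ABCDE")
        inter = interactions_from([("I1", [{"A", "B"}, {"C", "D"}, {"E"}])])
        net = build_comm_network(inter, eth)
        assert net.graph.number_of_nodes() == 5
        assert component_diversity(net) == 4

    def test_edgeless_graph_zero_diversity(self):
        eth = singleton_ethogram("AB")
        inter = interactions_from([("I1", [{"A"}, {"B"}])])
        assert component_diversity(build_comm_network(inter, eth)) == 0

    @pytest.mark.parametrize("sizes,expected", [
        ([6, 2, 2], 17), ([1, 1, 1], 0), ([2], 1),
    ])
    def test_impossible_pairs(self, sizes, expected):
        assert impossible_pairs(sizes) == expected

    def test_adjusted_density_two_group_toy(self):
        eth = Ethogram([Component("a1", "G1"), Component("a2", "G1"),
                        Component("b1", "G2"), Component("b2", "G2")])
        inter = interactions_from([("I1", [{"a1", "b1"}, {"a2", "b2"}])])
        net = build_comm_network(inter, eth)
        # 2 observed edges / (C(4,2)=6 possible - 2 impossible) = 0.5
        assert adjusted_density(net) == pytest.approx(0.5)

    def test_complete_allowed_graph_density_one(self):
        eth = Ethogram([Component("a1", "G1"), Component("a2", "G1"),
                        Component("b", "B"), Component("c", "C")])
        inter = interactions_from([
            ("I1", [{"a1", "b", "c"}, {"a2", "b", "c"}]),
        ])
        complete = build_comm_network(inter, eth)
        assert adjusted_density(complete) == pytest.approx(1.0)

    def test_singleton_groups_reduce_to_plain_density(self):
        eth = singleton_ethogram("ABCD")
        inter = interactions_from([("I1", [{"A", "B"}, {"C", "D"}, {"A", "C"}])])
        net = build_comm_network(inter, eth)
        assert adjusted_density(net) == pytest.approx(nx.density(net.graph))


class TestResamplingNulls:
    def _reference(self):
        eth = singleton_ethogram("ABCDEF")
        postures = [{"A", "B"}, {"B", "C"}, {"C", "D"}, {"D", "E"},
                    {"E", "F"}, {"A", "F"}, {"B", "E"}]
        inter = interactions_from([("I1", postures)])
        return postures_of(inter), build_comm_network(inter, eth)

    def test_full_subsample_reproduces_reference_diversity(self):
        postures, net = self._reference()
        res = diversity_jackknife(postures, component_diversity(net),
                                  n_sub=len(postures), n_perm=50, seed=0)
        assert (res.null_values == component_diversity(net)).all()
        assert res.significant is None

    def test_low_observed_flagged_significant_less(self):
        postures, _ = self._reference()
        res = diversity_jackknife(postures, observed_diversity=0,
                                  n_sub=6, n_perm=200, seed=0)
        assert res.significant == "less"

    def test_oversized_subsample_rejected(self):
        postures, _ = self._reference()
        with pytest.raises(ValueError):
            diversity_jackknife(postures, 4, n_sub=99, n_perm=10, seed=0)

    def test_full_node_subsample_reproduces_reference_density(self):
        _, net = self._reference()
        obs = adjusted_density(net)
        res = density_node_subsample_null(net, obs, net.graph.number_of_nodes(),
                                          n_perm=50, seed=0)
        assert np.allclose(res.null_values, obs)

    def test_complete_reference_always_density_one(self):
        eth = singleton_ethogram("ABCD")
        inter = interactions_from([("I1", [{"A", "B", "C", "D"}])])
        net = build_comm_network(inter, eth)
        res = density_node_subsample_null(net, 1.0, 3, n_perm=50, seed=0)
        assert np.allclose(res.null_values, 1.0)

    def test_too_small_node_subsample_rejected(self):
        _, net = self._reference()
        with pytest.raises(ValueError):
            density_node_subsample_null(net, 0.5, 1, n_perm=10, seed=0)


class TestModules:
    def test_single_clique_one_module_q_zero(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        nx.set_edge_attributes(g, 1.0, "weight")
        net = CommNetwork("x", g, {v: v for v in g.nodes})
        mods, q = detect_modules(net)
        assert len(set(mods.values())) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_graph_singleton_modules(self):
        g = nx.empty_graph(3)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        net = CommNetwork("x", g, {v: v for v in g.nodes})
        mods, q = detect_modules(net)
        assert len(set(mods.values())) == 3
        assert q == 0.0

    def test_q_matches_independent_recomputation(self):
        # closed-form weighted modularity from the returned partition
        rng = np.random.default_rng(4)
        g = nx.gnm_random_graph(12, 24, seed=4)
        g = nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes})
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.integers(1, 5))
        net = CommNetwork("x", g, {v: v for v in g.nodes})
        mods, q = detect_modules(net)
        w_total = sum(d["weight"] for _, _, d in g.edges(data=True))
        strength = dict(g.degree(weight="weight"))
        q_manual = 0.0
        for m in set(mods.values()):
            members = {v for v, mm in mods.items() if mm == m}
            w_in = sum(d["weight"] for u, v, d in g.edges(data=True)
                       if u in members and v in members)
            s = sum(strength[v] for v in members)
            q_manual += w_in / w_total - (s / (2 * w_total)) ** 2
        assert q == pytest.approx(q_manual, abs=1e-12)


class TestCrossPeriodModules:
    def _net(self, postures, codes, period):
        eth = singleton_ethogram(codes)
        return build_comm_network(interactions_from([("I1", postures)], period), eth)

    def test_identical_networks_all_retained(self):
        postures = [{"A", "B"}, {"C", "D"}]
        a = self._net(postures, "ABCD", "pre")
        b = self._net(postures, "ABCD", "late")
        flow = compare_modules(a, b)
        assert (flow["status"] == "retained").all()
        mapping = flow.set_index("component")
        assert (mapping["module_pre"] == mapping["module_late"]).all()

    def test_lost_component_flagged(self):
        a = self._net([{"A", "B"}, {"C", "B"}], "ABC", "pre")
        b = self._net([{"A", "B"}], "AB", "late")
        flow = compare_modules(a, b).set_index("component")
        assert flow.loc["C", "module_late"] == "LOST"

    def test_module_split_maps_one_source_to_two_sinks(self):
        pre = [{"A", "B"}, {"B", "C"}, {"C", "D"}, {"A", "D"},
               {"A", "C"}, {"B", "D"}] * 2
        late = [{"A", "B"}] * 4 + [{"C", "D"}] * 4
        a = self._net(pre, "ABCD", "pre")
        b = self._net(late, "ABCD", "late")
        flow = compare_modules(a, b)
        pre_mod = flow.set_index("component")["module_pre"]
        assert len(set(pre_mod)) == 1
        late_mods = flow.set_index("component")["module_late"]
        assert len(set(late_mods)) == 2

    def test_modality_loss_counts(self):
        comps = [Component(f"v{i}", f"v{i}", "acoustic") for i in range(4)]
        comps += [Component(f"t{i}", f"t{i}", "tactile") for i in range(2)]
        eth = Ethogram(comps)
        pre_postures = [{"v0", "v1"}, {"v2", "v3"}, {"t0", "t1"}]
        late_postures = [{"v0", "v1"}, {"t0", "t1"}]
        a = build_comm_network(interactions_from([("I1", pre_postures)], "pre"), eth)
        b = build_comm_network(interactions_from([("I1", late_postures)], "late"), eth)
        loss = modality_loss_summary(a, b, eth).set_index("modality")
        assert loss.loc["acoustic", "lost"] == 2
        assert loss.loc["acoustic", "total"] == 4
        assert loss.loc["acoustic", "fraction_lost"] == pytest.approx(0.5)
        assert loss.loc["tactile", "fraction_lost"] == 0.0
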