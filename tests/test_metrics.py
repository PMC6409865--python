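import math

import networkx as nx
import numpy as np
import pytest

import netloci as nl
from oracles import (
    brute_betweenness,
    floyd_warshall_distances,
    random_connected_gnp,
    random_gnp,
)


class TestBfsDistances:
    def test_chain(self, toys):
        assert nl.bfs_distances(toys["path4"], "a") == {"a": 0, "b": 1, "c": 2, "d": 3}

    def test_complete_graph(self, toys):
        d = nl.bfs_distances(toys["k4"], "b")
        assert d["b"] == 0
        assert all(d[v] == 1 for v in "acd")

    def test_unreachable_absent_from_mapping(self):
        net = nl.Interactome.from_edges([("a", "b"), ("c", "d")])
        assert set(nl.bfs_distances(net, "a")) == {"a", "b"}

    def test_unknown_source_is_error(self, toys):
        with pytest.raises(ValueError):
            nl.bfs_distances(toys["path4"], "nope")

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_floyd_warshall_oracle(self, seed):
        net = random_gnp(seed)
        oracle = floyd_warshall_distances(net)
        for source in sorted(net.nodes):
            mine = nl.bfs_distances(net, source)
            for target in sorted(net.nodes):
                expected = oracle[source][target]
                if math.isinf(expected):
                    assert target not in mine
                else:
                    assert mine[target] == expected


class TestAspl:
    def test_path_closed_forms(self, toys):
        p4 = toys["path4"]
        assert nl.node_aspl(p4, "a") == pytest.approx(2.0)
        assert nl.node_aspl(p4, "d") == pytest.approx(2.0)
        assert nl.node_aspl(p4, "b") == pytest.approx(4 / 3)

    def test_star_center(self, toys):
        assert nl.node_aspl(toys["star4"], "hub") == pytest.approx(1.0)

    def test_network_apl_both_normalizations(self, toys):
        p4 = toys["path4"]
        assert nl.network_apl(p4, "conventional") == pytest.approx(5 / 3)
        assert nl.network_apl(p4, "inclusive") == pytest.approx(1.0)
        assert nl.network_apl(toys["k4"], "conventional") == pytest.approx(1.0)

    def test_inclusive_normalization_counts_self_pairs_in_denominator(self, toys):
        # same distance total, denominator N(N+1)/2 instead of N(N-1)/2
        p4 = toys["path4"]
        ratio = nl.network_apl(p4, "conventional") / nl.network_apl(p4, "inclusive")
        assert ratio == pytest.approx(5 / 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_mean_node_aspl_equals_conventional_network_apl(self, seed):
        net = random_connected_gnp(seed)
        mean_aspl = np.mean([nl.node_aspl(net, v) for v in sorted(net.nodes)])
        assert mean_aspl == pytest.approx(nl.network_apl(net, "conventional"))

    def test_isolated_node_is_error(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        net = nl.Interactome(g)
        with pytest.raises(ValueError, match="reachable"):
            nl.node_aspl(net, "c")

    def test_disconnected_graph_is_error(self):
        net = nl.Interactome.from_edges([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="connected"):
            nl.network_apl(net)


class TestClustering:
    def test_complete_graph_everywhere_one(self, toys):
        assert all(
            nl.clustering_coefficient(toys["k4"], v) == pytest.approx(1.0)
            for v in "abcd"
        )

    def test_triangle_with_pendant_hub(self, toys):
        assert nl.clustering_coefficient(toys["triangle_pendant"], "a") == pytest.approx(
            1 / 3
        )

    def test_star_center_zero(self, toys):
        assert nl.clustering_coefficient(toys["star4"], "hub") == 0.0

    def test_degree_below_two_is_zero(self, toys):
        assert nl.clustering_coefficient(toys["path4"], "a") == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_and_networkx_agreement(self, seed):
        net = random_gnp(seed)
        ref = nx.clustering(net.to_networkx())
        for v in sorted(net.nodes):
            cc = nl.clustering_coefficient(net, v)
            assert 0.0 <= cc <= 1.0
            assert cc == pytest.approx(ref[v], abs=1e-12)


class TestBetweenness:
    def test_path_inner_and_outer(self, toys):
        bc = nl.betweenness_centrality(toys["path4"])
        assert bc["b"] == pytest.approx(2 / 3)
        assert bc["a"] == 0.0

    def test_star_center_one_leaves_zero(self, toys):
        bc = nl.betweenness_centrality(toys["star4"])
        assert bc["hub"] == pytest.approx(1.0)
        assert all(bc[v] == 0.0 for v in "abcd")

    def test_complete_graph_all_zero(self, toys):
        assert all(v == 0.0 for v in nl.betweenness_centrality(toys["k4"]).values())

    def test_barbell_bridge_endpoints_dominate(self, toys):
        bc = nl.betweenness_centrality(toys["barbell"])
        top2 = sorted(bc, key=bc.get, reverse=True)[:2]
        assert set(top2) == {"c", "d"}

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_path_enumeration_oracle(self, seed):
        net = random_gnp(seed)
        mine = nl.betweenness_centrality(net)
        oracle = brute_betweenness(net)
        for v in net.nodes:
            assert mine[v] == pytest.approx(oracle[v], abs=1e-9)
            assert 0.0 <= mine[v] <= 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_tree_betweenness_counts_pairs_through_node(self, seed):
        tree = nx.random_labeled_tree(30, seed=seed)
        tree = nx.relabel_nodes(tree, {v: f"t{v:02d}" for v in tree})
        net = nl.Interactome(tree)
        raw = nl.betweenness_centrality(net, normalized=False)
        nodes = sorted(net.nodes)
        for v in nodes:
            pairs_through = 0
            for i_idx in range(len(nodes)):
                for j_idx in range(i_idx + 1, len(nodes)):
                    i, j = nodes[i_idx], nodes[j_idx]
                    if v in (i, j):
                        continue
                    if v in nx.shortest_path(tree, i, j):
                        pairs_through += 1
            assert raw[v] == pytest.approx(pairs_through)

    @pytest.mark.parametrize("seed", range(5))
    def test_adding_edge_never_increases_distances(self, seed):
        net = random_connected_gnp(seed)
        before = floyd_warshall_distances(net)
        nodes = sorted(net.nodes)
        rng = np.random.default_rng(seed)
        g = net.to_networkx()
        absent = [
            (a, b)
            for i, a in enumerate(nodes)
            for b in nodes[i + 1 :]
            if not g.has_edge(a, b)
        ]
        if not absent:
            pytest.skip("complete graph")
        a, b = absent[rng.integers(len(absent))]
        g.add_edge(a, b)
        after = floyd_warshall_distances(nl.Interactome(g))
        for x in nodes:
            for y in nodes:
                assert after[x][y] <= before[x][y]


class TestComputeAllMetrics:
    def test_complete_graph_records(self, toys):
        records = nl.compute_all_metrics(toys["k4"])
        assert len(records) == 4
        for r in records:
            assert (r.degree, r.aspl, r.cc, r.bc) == (3, 1.0, 1.0, 0.0)

    def test_path_single_target(self, toys):
        (r,) = nl.compute_all_metrics(
            toys["path4"], nl.GeneSet(name="t", members=("b",))
        )
        assert r.degree == 2
        assert r.aspl == pytest.approx(4 / 3)
        assert r.cc == 0.0
        assert r.bc == pytest.approx(2 / 3)

    def test_absent_targets_skipped_and_all_absent_error(self, toys, caplog):
        records = nl.compute_all_metrics(toys["path4"], ["b", "nope"])
        assert [r.gene for r in records] == ["b"]
        with pytest.raises(ValueError):
            nl.compute_all_metrics(toys["path4"], ["nope"])

    def test_published_fixture_is_loaded_not_recomputed(self, table2):
        by_gene = {m.gene: m for m in table2}
        tp53 = by_gene["TP53"]
        assert (tp53.degree, tp53.aspl, tp53.cc) == (178, 2.57, 0.39)
        assert tp53.bc == pytest.approx(0.117)
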