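import itertools
import math

import networkx as nx
import pytest

from _oracles import (
    exhaustive_betweenness,
    floyd_warshall_distances,
    random_simple_graph,
)
from conftest import as_network
from ppitopo.graph_core import build_network
from ppitopo.metrics import (
    betweenness_centrality,
    closeness_centrality,
    compute_node_metrics,
    degree_map,
    network_summary,
    write_node_metrics,
)


def complete(n):
    return build_network(
        [(f"K{i}", f"K{j}") for i, j in itertools.combinations(range(n), 2)]
    )


def star(n_leaves):
    return build_network([("HUB", f"L{i}") for i in range(n_leaves)])


class TestDegree:
    def test_star_degrees(self):
        deg = degree_map(star(4))
        assert deg["HUB"] == 4
        assert all(deg[f"L{i}"] == 1 for i in range(4))

    def test_empty_network(self):
        assert degree_map(build_network([])) == {}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_edge_scan_oracle(self, seed):
        net = as_network(random_simple_graph(10, 0.3, seed))
        deg = degree_map(net)
        for v in net.nodes:
            assert deg[v] == sum(1 for e in net.edges if v in e)


class TestBetweenness:
    def test_path_interior_node_carries_all_flow(self):
        net = build_network([("A", "B"), ("B", "C")])
        bc = betweenness_centrality(net, normalized=True)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}
        raw = betweenness_centrality(net, normalized=False)
        assert raw["B"] == 1.0

    def test_complete_graph_has_no_interior_vertices(self):
        bc = betweenness_centrality(complete(5))
        assert all(v == 0.0 for v in bc.values())

    def test_bridge_between_cliques_dominates(self, bridged_cliques):
        raw = betweenness_centrality(bridged_cliques, normalized=False)
        norm = betweenness_centrality(bridged_cliques, normalized=True)
        assert raw["B"] == pytest.approx(9.0)
        assert norm["B"] == pytest.approx(9 / 15)
        # clique anchors are second, confirmed by the exhaustive oracle
        oracle = exhaustive_betweenness(bridged_cliques.graph, normalized=False)
        assert raw["A1"] == raw["C1"] == pytest.approx(8.0)
        for v in bridged_cliques.nodes:
            assert raw[v] == pytest.approx(oracle[v], abs=1e-12)

    @pytest.mark.parametrize("seed", range(200))
    def test_brandes_equals_exhaustive_geodesic_enumeration(self, seed):
        """Dependency accumulation must agree with brute-force geodesic counting."""
        n = 3 + seed % 7  # sizes 3..9
        net = as_network(random_simple_graph(n, 0.35, seed))
        got = betweenness_centrality(net, normalized=True)
        expected = exhaustive_betweenness(net.graph, normalized=True)
        for v in net.nodes:
            assert got[v] == pytest.approx(expected[v], abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_cross_check_against_networkx(self, seed):
        net = as_network(random_simple_graph(12, 0.25, seed))
        got = betweenness_centrality(net, normalized=True)
        ref = nx.betweenness_centrality(net.graph, normalized=True)
        for v in net.nodes:
            assert got[v] == pytest.approx(ref[v], abs=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_tree_identity_raw_bc_sums_to_excess_path_length(self, seed):
        """On a tree, total raw BC equals sum over pairs of (d(s,t) - 1)."""
        tree = nx.random_labeled_tree(10, seed=seed)
        net = as_network(nx.relabel_nodes(tree, {i: f"T{i}" for i in tree.nodes}))
        raw = betweenness_centrality(net, normalized=False)
        fw = floyd_warshall_distances(net.nodes, net.edges)
        expected = sum(
            fw[(s, t)] - 1 for s, t in itertools.combinations(net.nodes, 2)
        )
        assert sum(raw.values()) == pytest.approx(expected, abs=1e-9)

    def test_normalized_values_stay_in_unit_interval(self):
        for seed in range(20):
            net = as_network(random_simple_graph(11, 0.2, seed))
            assert all(0 <= v <= 1 for v in betweenness_centrality(net).values())


class TestCloseness:
    def test_complete_graph_is_maximally_close(self):
        assert all(v == 1.0 for v in closeness_centrality(complete(4)).values())

    def test_path_endpoints_and_centre(self):
        net = build_network([("A", "B"), ("B", "C")])
        cc = closeness_centrality(net)
        assert cc["A"] == pytest.approx(2 / 3)
        assert cc["B"] == pytest.approx(1.0)
        assert cc["C"] == pytest.approx(2 / 3)

    def test_isolated_node_scores_zero(self):
        net = build_network([("A", "B")], extra_nodes={"Z"})
        assert closeness_centrality(net)["Z"] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_component_wise_distance_oracle(self, seed):
        net = as_network(random_simple_graph(9, 0.3, seed))
        fw = floyd_warshall_distances(net.nodes, net.edges)
        got = closeness_centrality(net)
        for v in net.nodes:
            dists = [fw[(v, u)] for u in net.nodes
                     if u != v and math.isfinite(fw[(v, u)])]
            expected = len(dists) / sum(dists) if dists else 0.0
            assert got[v] == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= got[v] <= 1.0


class TestNetworkSummary:
    def test_path_p4(self, path4):
        s = network_summary(path4)
        assert s.avg_degree == pytest.approx(1.5)
        assert s.diameter == 3
        assert s.mspl == pytest.approx(10 / 6)

    def test_complete_k4(self):
        s = network_summary(complete(4))
        assert (s.avg_degree, s.diameter, s.mspl) == (3.0, 1, 1.0)

    def test_edgeless_network_reports_zeros(self, caplog):
        net = build_network([], extra_nodes={"A", "B"})
        with caplog.at_level("WARNING"):
            s = network_summary(net)
        assert (s.mspl, s.diameter) == (0.0, 0)
        assert "no connected pairs" in caplog.text

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            network_summary(build_network([]))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_all_pairs_oracle(self, seed):
        net = as_network(random_simple_graph(10, 0.25, seed))
        fw = floyd_warshall_distances(net.nodes, net.edges)
        finite = [
            fw[(s, t)]
            for s, t in itertools.combinations(net.nodes, 2)
            if math.isfinite(fw[(s, t)])
        ]
        s = network_summary(net)
        assert s.avg_degree == pytest.approx(2 * net.n_edges / net.n_nodes)
        if finite:
            assert s.mspl == pytest.approx(sum(finite) / len(finite))
            assert s.diameter == max(finite)


class TestNodeMetricsTable:
    def test_star_record_values(self):
        records = {m.symbol: m for m in compute_node_metrics(star(3))}
        hub = records["HUB"]
        assert (hub.degree, hub.betweenness, hub.closeness) == (3, 1.0, 1.0)
        leaf = records["L0"]
        assert leaf.degree == 1 and leaf.betweenness == 0.0
        assert leaf.closeness == pytest.approx(3 / 5)

    def test_single_isolated_node(self):
        (m,) = compute_node_metrics(build_network([], extra_nodes={"A"}))
        assert (m.degree, m.betweenness, m.closeness) == (0, 0.0, 0.0)

    def test_consistent_with_individual_operations_and_ordered(self):
        net = as_network(random_simple_graph(10, 0.3, 42))
        records = compute_node_metrics(net)
        deg, bc, cc = degree_map(net), betweenness_centrality(net), closeness_centrality(net)
        for m in records:
            assert m.degree == deg[m.symbol]
            assert m.betweenness == bc[m.symbol]
            assert m.closeness == cc[m.symbol]
        keys = [(-m.degree, m.symbol) for m in records]
        assert keys == sorted(keys)

    def test_tsv_writer_uses_fixed_eight_decimal_format(self, tmp_path):
        net = build_network([("A", "B"), ("B", "C")])
        out = tmp_path / "metrics.tsv"
        write_node_metrics(compute_node_metrics(net), out)
        lines = out.read_text().splitlines()
        assert lines[0] == "symbol\tdegree\tbetweenness\tcloseness"
        assert lines[1] == "B\t2\t1.00000000\t1.00000000"
        assert lines[2] == "A\t1\t0.00000000\t0.66666667"
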