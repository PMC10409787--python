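"""Network construction, betweenness, density, hubs and module detection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from vitnet.io import CorrelationMatrix
from vitnet.network import (
    betweenness,
    build_network,
    delineate_hubs,
    density,
    detect_modules,
    summarize,
)


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Independent oracle: enumerate all shortest paths between every pair
    by breadth-limited path enumeration and count pass-through fractions."""
    nodes = list(g.nodes)
    b = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            d = nx.shortest_path_length(g, s, t)
        except nx.NetworkXNoPath:
            continue
        paths = [
            p for p in nx.all_simple_paths(g, s, t, cutoff=d) if len(p) - 1 == d
        ]
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            b[v] += through / sigma
    return b


def corr_from_dict(ids, entries) -> CorrelationMatrix:
    n = len(ids)
    r = np.eye(n)
    pos = {g: i for i, g in enumerate(ids)}
    for (a, bnode), val in entries.items():
        r[pos[a], pos[bnode]] = r[pos[bnode], pos[a]] = val
    return CorrelationMatrix(ids, r)


class TestBuildNetwork:
    def test_threshold_is_inclusive_at_035(self):
        corr = corr_from_dict(["A", "B", "C", "D"], {("A", "B"): 0.35})
        net = build_network(corr, threshold=0.35)
        assert net.has_edge("A", "B") and net["A"]["B"]["weight"] == 0.35

    def test_sign_rule_and_threshold(self):
        corr = corr_from_dict(
            ["A", "B", "C"], {("A", "B"): 0.5, ("A", "C"): 0.2, ("B", "C"): -0.6}
        )
        net = build_network(corr, threshold=0.35)
        assert list(net.edges) == [("A", "B")]

    def test_all_below_threshold_yields_empty_network(self, caplog):
        corr = corr_from_dict(["A", "B", "C"], {("A", "B"): 0.1})
        with caplog.at_level("WARNING", logger="vitnet"):
            net = build_network(corr, 0.35)
        assert net.number_of_nodes() == 0
        assert any("EMPTY_NETWORK" in r.message for r in caplog.records)

    def test_isolated_nodes_dropped(self):
        corr = corr_from_dict(["A", "B", "C"], {("A", "B"): 0.9})
        net = build_network(corr, 0.35)
        assert set(net.nodes) == {"A", "B"}

    def test_nonpositive_threshold_rejected(self):
        corr = corr_from_dict(["A", "B"], {("A", "B"): 0.5})
        with pytest.raises(ValueError, match="positive"):
            build_network(corr, 0.0, positive_only=True)

    def test_pvalue_filter(self):
        r = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.1], [0.5, 0.1, 1.0]])
        p = np.array([[0.0, 0.001, 0.5], [0.001, 0.0, 0.9], [0.5, 0.9, 0.0]])
        corr = CorrelationMatrix(["A", "B", "C"], r, p)
        net = build_network(corr, 0.35, p_max=0.05)
        assert list(net.edges) == [("A", "B")]


class TestBetweenness:
    def test_path_graph_center_mediates_one_pair(self):
        cent = betweenness(nx.path_graph(["A", "B", "C"]))
        assert cent.b == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_five_node_star_center_scores_all_leaf_pairs(self):
        g = nx.star_graph(4)  # center 0, four leaves
        cent = betweenness(g)
        assert cent.b[0] == 6.0  # C(4,2) leaf pairs
        assert all(cent.b[v] == 0.0 for v in range(1, 5))

    def test_complete_graph_all_zero(self):
        cent = betweenness(nx.complete_graph(4))
        assert set(cent.b.values()) == {0.0}

    def test_agrees_with_path_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
            cent = betweenness(g)
            oracle = brute_force_betweenness(g)
            for v in g.nodes:
                assert cent.b[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("C", "D")])
        cent = betweenness(g)
        assert set(cent.b.values()) == {0.0}


class TestDensity:
    def test_complete_graph_density_one(self):
        assert density(nx.complete_graph(4)) == 1.0

    def test_path_graph_closed_form(self):
        assert density(nx.path_graph(4)) == 0.5

    def test_empty_edge_set(self):
        g = nx.empty_graph(120)
        assert density(g) == 0.0

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            density(nx.empty_graph(1))

    def test_adding_edge_strictly_increases_density(self):
        g = nx.path_graph(5)
        before = density(g)
        g.add_edge(0, 4)
        assert density(g) > before


class TestHubDelineation:
    def test_star_center_is_the_hub(self):
        cent = betweenness(nx.star_graph(5))
        assert delineate_hubs(cent, "top_k", k=1) == [0]

    def test_no_elevation_gives_empty_set(self):
        cent = betweenness(nx.complete_graph(4))
        assert delineate_hubs(cent, "mean_plus_sd") == []

    def test_tie_break_by_degree_then_id(self):
        # two tied betweenness maxima with different degrees
        g = nx.Graph()
        g.add_edges_from([("a", "m1"), ("m1", "b"), ("b", "m2"), ("m2", "a")])
        g.add_edge("m1", "x")  # raises m1's degree, not its tie rank vs m2
        cent = betweenness(g)
        from vitnet.network import CentralityTable

        flat = CentralityTable(
            {v: 1.0 for v in ["p", "q"]}, {v: 0.5 for v in ["p", "q"]},
            {"p": 2, "q": 2},
        )
        assert delineate_hubs(flat, "top_k", k=1) == ["p"]  # id tie-break
        uneven = CentralityTable(
            {"p": 1.0, "q": 1.0}, {"p": 0.5, "q": 0.5}, {"p": 2, "q": 5}
        )
        assert delineate_hubs(uneven, "top_k", k=1) == ["q"]  # degree wins

    def test_k_exceeding_n_rejected(self):
        cent = betweenness(nx.path_graph(3))
        with pytest.raises(ValueError, match="exceeds node count"):
            delineate_hubs(cent, "top_k", k=5)


class TestModules:
    def two_k5s(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        nx.set_edge_attributes(g, 1.0, "weight")
        return g

    @pytest.mark.parametrize("method", ["louvain", "girvan_newman"])
    def test_two_disjoint_cliques_recovered_with_half_modularity(self, method):
        part = detect_modules(self.two_k5s(), method, seed=1)
        assert part.n_modules == 2
        mods = part.modules()
        assert sorted(sorted(m) for m in mods.values()) == [
            [0, 1, 2, 3, 4],
            [5, 6, 7, 8, 9],
        ]
        assert part.modularity == pytest.approx(0.5)

    @pytest.mark.parametrize("method", ["louvain", "girvan_newman"])
    def test_single_clique_is_one_module_q_zero(self, method):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = detect_modules(g, method, seed=0)
        assert part.n_modules == 1 and part.modularity == pytest.approx(0.0)

    def test_louvain_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        g = nx.planted_partition_graph(4, 15, 0.6, 0.02, seed=7)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = detect_modules(g, "louvain", seed=7)
        truth = [v // 15 for v in sorted(g.nodes)]
        found = [part.assignment[v] for v in sorted(g.nodes)]
        assert adjusted_rand_score(truth, found) >= 0.9

    def test_modularity_recomputable_from_partition(self):
        g = nx.planted_partition_graph(3, 8, 0.7, 0.05, seed=3)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = detect_modules(g, "louvain", seed=3)
        q = nx.community.modularity(
            g, part.modules().values(), weight="weight"
        )
        assert part.modularity == pytest.approx(q)

    def test_edgeless_graph_singleton_modules(self):
        part = detect_modules(nx.empty_graph(3), "louvain")
        assert part.n_modules == 3 and part.modularity == 0.0


class TestSummarize:
    def test_complete_graph_summary(self):
        g = nx.complete_graph(4)
        s = summarize(g)
        assert (s.n, s.m, s.d, s.mean_degree) == (4, 6, 1.0, 3.0)

    def test_two_k5_summary_with_partition(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        nx.set_edge_attributes(g, 1.0, "weight")
        part = detect_modules(g, "louvain", seed=0)
        s = summarize(g, part=part)
        assert s.Q == pytest.approx(0.5)

    def test_edgeless_graph(self):
        g = nx.empty_graph(3)
        s = summarize(g, part=detect_modules(g, "louvain"))
        assert s.d == 0.0 and s.Q == 0.0
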