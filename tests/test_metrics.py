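"""Centrality and community structure against closed forms and oracles."""

import numpy as np
import pytest

from acunet import (RefusalError, ValidationError, WeightedGraph,
                    betweenness_centrality, brute_force_modularity_max,
                    centrality_table, degree_centrality, hub_scores,
                    kruskal_backbone, louvain_partition, modularity)
from conftest import betweenness_by_enumeration, random_graph


def path_graph(labels, weight=0.5):
    return WeightedGraph.from_edges(
        list(labels), [(a, b, weight) for a, b in zip(labels, labels[1:])])


def two_triangles(bridge=False):
    edges = [("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0),
             ("D", "E", 1.0), ("E", "F", 1.0), ("D", "F", 1.0)]
    if bridge:
        edges.append(("C", "D", 1.0))
    return WeightedGraph.from_edges(list("ABCDEF"), edges)


class TestDegree:
    def test_corpus_hub_degree(self, table2):
        from acunet import cooccurrence_graph
        ct = degree_centrality(cooccurrence_graph(table2))
        assert ct.loc["CV4", "degree"] == 26

    def test_star_center(self):
        g = WeightedGraph.from_edges(
            ["C", "L1", "L2", "L3", "L4"],
            [("C", f"L{i}", 0.25) for i in range(1, 5)])
        ct = degree_centrality(g)
        assert ct.loc["C", "degree"] == 4
        assert ct.loc["C", "strength"] == pytest.approx(1.0)

    def test_triangle_strength(self):
        g = WeightedGraph.from_edges(
            ["A", "B", "C"], [("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.5)])
        ct = degree_centrality(g)
        assert ct.loc["B", "strength"] == pytest.approx(1.7)


class TestBetweenness:
    def test_path3_middle(self):
        ct = betweenness_centrality(path_graph("ABC"))
        assert ct.loc["B", "betweenness_norm"] == pytest.approx(1.0)

    def test_path4_interior(self):
        ct = betweenness_centrality(path_graph("ABCD"))
        assert ct.loc["B", "betweenness_norm"] == pytest.approx(2 / 3)
        assert ct.loc["C", "betweenness_norm"] == pytest.approx(2 / 3)

    def test_tree_leaves_are_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = random_graph(rng, 7)
            t = kruskal_backbone(g).as_graph(g)
            ct = betweenness_centrality(t)
            for u in t.nodes:
                if t.degree(u) == 1:
                    assert ct.loc[u, "betweenness_raw"] == 0.0

    @pytest.mark.parametrize("use_weights", [False, True])
    def test_matches_enumeration_oracle(self, use_weights):
        rng = np.random.default_rng(11)
        for _ in range(100):
            g = random_graph(rng, int(rng.integers(3, 8)))
            ct = betweenness_centrality(g, use_weights=use_weights)
            oracle = betweenness_by_enumeration(g, use_weights=use_weights)
            for u in g.nodes:
                assert ct.loc[u, "betweenness_raw"] == pytest.approx(
                    oracle[u], abs=1e-9)

    def test_modes_coincide_on_trees(self, table2):
        from acunet import cooccurrence_graph
        g = cooccurrence_graph(table2)
        t = kruskal_backbone(g).as_graph(g)
        unw = betweenness_centrality(t, use_weights=False)
        wtd = betweenness_centrality(t, use_weights=True)
        assert np.allclose(unw["betweenness_raw"], wtd["betweenness_raw"])

    def test_networkx_cross_check(self):
        import networkx as nx
        rng = np.random.default_rng(23)
        g = random_graph(rng, 7)
        G = nx.Graph()
        G.add_nodes_from(g.nodes)
        for u, v, w in g.edges():
            G.add_edge(u, v, dist=1.0 - w)
        mine = betweenness_centrality(g, use_weights=True)
        ref = nx.betweenness_centrality(G, weight="dist", normalized=True)
        for u in g.nodes:
            assert mine.loc[u, "betweenness_norm"] == pytest.approx(ref[u], abs=1e-9)

    def test_weight_one_edge_rejected(self):
        g = WeightedGraph.from_edges(["A", "B"], [("A", "B", 1.0)])
        with pytest.raises(ValidationError):
            betweenness_centrality(g, use_weights=True)


class TestModularity:
    def test_single_community_is_zero(self):
        g = two_triangles(bridge=True)
        part = {u: 0 for u in g.nodes}
        assert modularity(g, part, use_weights=False) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        g = two_triangles()
        part = {"A": 0, "B": 0, "C": 0, "D": 1, "E": 1, "F": 1}
        assert modularity(g, part, use_weights=False) == pytest.approx(0.5)

    def test_bridged_triangles_closed_form(self):
        g = two_triangles(bridge=True)
        part = {"A": 0, "B": 0, "C": 0, "D": 1, "E": 1, "F": 1}
        expected = 2 * (3 / 7 - (7 / 14) ** 2)
        assert modularity(g, part, use_weights=False) == pytest.approx(expected)

    def test_relabel_and_permutation_invariance(self):
        rng = np.random.default_rng(9)
        g = random_graph(rng, 6)
        part = {u: i % 2 for i, u in enumerate(g.nodes)}
        q1 = modularity(g, part)
        relabeled = {u: 1 - c for u, c in part.items()}
        assert modularity(g, relabeled) == pytest.approx(q1)
        g2 = WeightedGraph(list(reversed(g.nodes)))
        for u, v, w in g.edges():
            g2.add_edge(u, v, w)
        assert modularity(g2, part) == pytest.approx(q1)

    def test_networkx_cross_check(self):
        import networkx as nx
        rng = np.random.default_rng(13)
        g = random_graph(rng, 7)
        part = {u: i % 3 for i, u in enumerate(g.nodes)}
        G = nx.Graph()
        for u, v, w in g.edges():
            G.add_edge(u, v, weight=w)
        comms = [{u for u in g.nodes if part[u] == c} for c in range(3)]
        ref = nx.community.modularity(G, [c for c in comms if c], weight="weight")
        assert modularity(g, part) == pytest.approx(ref)

    def test_edgeless_rejected(self):
        g = WeightedGraph(["A", "B"])
        with pytest.raises(ValidationError):
            modularity(g, {"A": 0, "B": 0})


class TestLouvain:
    def test_two_disjoint_triangles(self):
        p = louvain_partition(two_triangles(), use_weights=False)
        assert p.n_communities == 2
        assert p.Q == pytest.approx(0.5)

    def test_bridged_triangles(self):
        p = louvain_partition(two_triangles(bridge=True), use_weights=False)
        assert p.n_communities == 2
        assert {frozenset(c) for c in p.communities()} == {
            frozenset("ABC"), frozenset("DEF")}

    def test_never_below_singleton_partition(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            g = random_graph(rng, int(rng.integers(3, 9)))
            p = louvain_partition(g)
            singletons = {u: i for i, u in enumerate(g.nodes)}
            assert p.Q >= modularity(g, singletons) - 1e-12

    def test_near_optimal_on_small_graphs(self):
        rng = np.random.default_rng(19)
        hits = 0
        n_graphs = 50
        for _ in range(n_graphs):
            g = random_graph(rng, int(rng.integers(4, 9)))
            p = louvain_partition(g)
            opt = brute_force_modularity_max(g)
            assert p.Q <= opt.Q + 1e-9
            if p.Q >= opt.Q - 0.05:
                hits += 1
        assert hits / n_graphs >= 0.95

    def test_corpus_backbone_three_communities(self, network_report):
        assert network_report.partition.n_communities == 3

    def test_seeded_random_restarts_reproducible(self):
        g = two_triangles(bridge=True)
        p1 = louvain_partition(g, order_policy="seeded-random", seed=1, restarts=5)
        p2 = louvain_partition(g, order_policy="seeded-random", seed=1, restarts=5)
        assert p1.assignment == p2.assignment

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValidationError):
            louvain_partition(two_triangles(), order_policy="roulette")

    def test_edgeless_rejected(self):
        with pytest.raises(ValidationError):
            louvain_partition(WeightedGraph(["A", "B"]))


class TestModularityOracle:
    def test_two_triangles_optimum(self):
        opt = brute_force_modularity_max(two_triangles(), use_weights=False)
        assert opt.Q == pytest.approx(0.5)
        assert opt.n_communities == 2

    def test_single_edge_optimum_is_one_community(self):
        g = WeightedGraph.from_edges(["A", "B"], [("A", "B", 1.0)])
        opt = brute_force_modularity_max(g, use_weights=False)
        assert opt.n_communities == 1
        assert opt.Q == pytest.approx(0.0)

    def test_refuses_large_graphs(self):
        g = WeightedGraph([chr(65 + i) for i in range(11)])
        with pytest.raises(RefusalError):
            brute_force_modularity_max(g)


def test_corpus_hub_regression(network_report):
    """CV4, SP6 and SP10 stay in the top 4 combined-centrality scores."""
    scores = hub_scores(centrality_table(network_report.backbone_graph))
    top4 = set(scores.sort_values(ascending=False).head(4).index)
    assert {"CV4", "SP6", "SP10"} <= top4
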