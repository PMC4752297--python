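"""Betweenness centrality: worked examples, oracle equivalence, invariants."""

from __future__ import annotations

import numpy as np
import pytest

from pathcent.centrality import (
    brute_force_betweenness,
    edge_betweenness,
    node_betweenness,
)
from pathcent.binarize import BinaryGraph

from conftest import graph_from_edges, random_graph, to_networkx


def assert_tables_close(fast, oracle, tol=1e-9):
    assert fast.node_scores.keys() == oracle.node_scores.keys()
    for v in fast.node_scores:
        assert fast.node_scores[v] == pytest.approx(oracle.node_scores[v], abs=tol)
    assert fast.edge_scores.keys() == oracle.edge_scores.keys()
    for e in fast.edge_scores:
        assert fast.edge_scores[e] == pytest.approx(oracle.edge_scores[e], abs=tol)


class TestWorkedExamples:
    def test_path_of_three_normalized(self):
        g = graph_from_edges([("a", "b"), ("b", "c")])
        table = node_betweenness(g, normalized=True)
        assert table.node_scores["b"] == pytest.approx(1.0)
        assert table.node_scores["a"] == 0.0 and table.node_scores["c"] == 0.0

    def test_star_center_is_one(self):
        g = graph_from_edges([("h", leaf) for leaf in "abcd"])
        table = node_betweenness(g, normalized=True)
        assert table.node_scores["h"] == pytest.approx(1.0)  # raw 6 / divisor 6
        assert all(table.node_scores[leaf] == 0.0 for leaf in "abcd")

    def test_five_cycle_uniform_one_sixth(self):
        nodes = ["a", "b", "c", "d", "e"]
        g = graph_from_edges(list(zip(nodes, nodes[1:] + nodes[:1])))
        table = node_betweenness(g, normalized=True)
        for v in nodes:
            assert table.node_scores[v] == pytest.approx(1 / 6)
        raw = brute_force_betweenness(g)
        for v in nodes:
            assert raw.node_scores[v] == pytest.approx(1.0)

    def test_path_edge_scores(self):
        g = graph_from_edges([("a", "b"), ("b", "c")])
        table = edge_betweenness(g)
        assert table.edge_scores[("a", "b")] == pytest.approx(2.0)
        assert table.edge_scores[("b", "c")] == pytest.approx(2.0)

    def test_triangle_edges_all_one(self):
        g = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        table = edge_betweenness(g)
        assert all(s == pytest.approx(1.0) for s in table.edge_scores.values())

    def test_single_edge_oracle(self):
        g = graph_from_edges([("a", "b")])
        oracle = brute_force_betweenness(g)
        assert oracle.node_scores == {"a": 0.0, "b": 0.0}
        assert oracle.edge_scores[("a", "b")] == pytest.approx(1.0)


class TestErrors:
    def test_empty_graph_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            node_betweenness(BinaryGraph(directed=False))

    def test_small_graph_normalization_warns_and_zeroes(self, caplog):
        g = graph_from_edges([("a", "b")])
        with caplog.at_level("WARNING"):
            table = node_betweenness(g, normalized=True)
        assert all(v == 0.0 for v in table.node_scores.values())
        assert "normalization" in caplog.text

    def test_brute_force_refuses_large_graphs(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 16, p=0.3)
        with pytest.raises(ValueError, match="15"):
            brute_force_betweenness(g)


class TestOracleEquivalence:
    def test_random_graphs_match_brute_force(self):
        """Brandes equals explicit path enumeration on many small graphs."""
        rng = np.random.default_rng(12345)
        for trial in range(60):
            n = int(rng.integers(4, 13))
            g = random_graph(rng, n, p=float(rng.uniform(0.2, 0.7)))
            fast = edge_betweenness(g)  # carries raw node + edge scores
            oracle = brute_force_betweenness(g)
            assert_tables_close(fast, oracle)

    def test_matches_networkx_on_random_graphs(self):
        """Independent cross-check against networkx's implementation."""
        import networkx as nx

        rng = np.random.default_rng(999)
        for trial in range(20):
            g = random_graph(rng, int(rng.integers(5, 20)), p=0.35)
            table = node_betweenness(g, normalized=True)
            expected = nx.betweenness_centrality(to_networkx(g), normalized=True)
            for v, score in expected.items():
                assert table.node_scores[v] == pytest.approx(score, abs=1e-9)
            raw_edges = nx.edge_betweenness_centrality(to_networkx(g), normalized=False)
            edge_table = edge_betweenness(g)
            for (u, v), score in raw_edges.items():
                assert edge_table.edge_scores[g.edge_key(u, v)] == pytest.approx(
                    score, abs=1e-9
                )

    def test_directed_graph_matches_networkx(self):
        import networkx as nx

        edges = [("a", "b"), ("b", "c"), ("c", "a"), ("b", "d"), ("d", "a")]
        g = graph_from_edges(edges, directed=True)
        table = node_betweenness(g, normalized=True)
        expected = nx.betweenness_centrality(to_networkx(g), normalized=True)
        for v, score in expected.items():
            assert table.node_scores[v] == pytest.approx(score, abs=1e-9)
        oracle = brute_force_betweenness(g)
        raw = nx.betweenness_centrality(to_networkx(g), normalized=False)
        for v, score in raw.items():
            assert oracle.node_scores[v] == pytest.approx(score, abs=1e-9)


class TestInvariants:
    def test_conservation_edge_sum_equals_distance_sum(self):
        """Σ raw edge betweenness = Σ shortest-path lengths over connected pairs."""
        import networkx as nx

        rng = np.random.default_rng(777)
        for trial in range(25):
            g = random_graph(rng, int(rng.integers(4, 15)), p=0.3)
            if g.n_edges == 0:
                continue
            table = edge_betweenness(g)
            nxg = to_networkx(g)
            dist_sum = sum(
                d
                for s, lengths in nx.all_pairs_shortest_path_length(nxg)
                for t, d in lengths.items()
                if s < t
            )
            assert sum(table.edge_scores.values()) == pytest.approx(dist_sum)

    def test_degree_one_nodes_score_zero(self):
        rng = np.random.default_rng(4242)
        for trial in range(10):
            g = random_graph(rng, 10, p=0.3)
            if g.n_edges == 0:
                continue
            adj = g.neighbors()
            table = node_betweenness(g, normalized=False)
            for v, nbrs in adj.items():
                if len(nbrs) == 1:
                    assert table.node_scores[v] == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(31)
        g = random_graph(rng, 9, p=0.4)
        table = node_betweenness(g, normalized=True)
        mapping = {k: f"z{i:02d}" for i, k in enumerate(sorted(g.nodes, reverse=True))}
        relabeled = graph_from_edges(
            [(mapping[u], mapping[v]) for (u, v) in g.edges],
            nodes=[mapping[k] for k in g.nodes],
        )
        rtable = node_betweenness(relabeled, normalized=True)
        for v in g.nodes:
            assert rtable.node_scores[mapping[v]] == pytest.approx(
                table.node_scores[v]
            )

    def test_disconnected_components_normalize_by_global_n(self):
        # two triangles sharing no nodes; pairs across components contribute 0
        g = graph_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        table = node_betweenness(g, normalized=True)
        assert all(v == 0.0 for v in table.node_scores.values())
        assert table.n_nodes == 6

    def test_edge_insertion_consistency_with_oracle(self):
        """After adding an edge, fast scores still equal the recomputed oracle."""
        rng = np.random.default_rng(55)
        g = random_graph(rng, 8, p=0.3)
        missing = [
            (u, v)
            for i, u in enumerate(sorted(g.nodes))
            for v in sorted(g.nodes)[i + 1 :]
            if (u, v) not in g.edges
        ]
        if missing:
            u, v = missing[0]
            from pathcent.binarize import BinaryRelation, RelationRule

            g.add_relation(u, v, BinaryRelation(u, v, RelationRule.REACTANT_PRODUCT, "extra"))
        assert_tables_close(edge_betweenness(g), brute_force_betweenness(g))
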