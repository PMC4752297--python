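"""Betweenness centrality on the binary-relation graph.

Betweenness measures how often a node or edge lies on shortest paths
between other nodes: for a node v,

    C_B(v) = sum over pairs s != t (s, t != v) of sigma_st(v) / sigma_st

where sigma_st counts shortest s–t paths and sigma_st(v) those passing
through v as an intermediate (endpoints are never intermediates).  Edge
betweenness replaces "through v" with "along edge e".  Pairs in different
components contribute nothing.

The fast path is Brandes' single-source accumulation over BFS shortest-path
DAGs — exact in O(n·m) for unweighted graphs — with a dependency variant
that scores edges in the same sweep.  ``brute_force_betweenness``
re-derives both scores by explicitly enumerating every shortest path per
pair; it exists purely as an independent oracle for tests and refuses
graphs with more than 15 nodes.

Conventions (each recorded in :class:`CentralityTable`): undirected pairs
are unordered; node scores are normalized by (n-1)(n-2)/2 (undirected) or
(n-1)(n-2) (directed) with n the whole graph's node count, also on
disconnected graphs; edge scores are reported raw, since only their ranking
is used downstream.
"""

from __future__ import annotations

import itertools
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

from .binarize import BinaryGraph

logger = logging.getLogger(__name__)

#: Hard cap for the explicit path-enumeration oracle.
BRUTE_FORCE_MAX_NODES = 15


@dataclass
class CentralityTable:
    """Node and edge betweenness scores plus the conventions that shaped them."""

    node_scores: dict[str, float]
    edge_scores: dict[tuple[str, str], float]
    normalized: bool
    directed: bool
    n_nodes: int
    labels: dict[str, str] = field(default_factory=dict)

    def top_nodes(self, k: int) -> list[tuple[str, float]]:
        """Highest-scoring nodes; ties broken by label then key."""
        order = sorted(
            self.node_scores.items(),
            key=lambda kv: (-kv[1], self.labels.get(kv[0], kv[0]), kv[0]),
        )
        return order[:k]


def _brandes(graph: BinaryGraph) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Raw node and edge betweenness via Brandes accumulation (unweighted)."""
    adj = graph.neighbors()
    node_bc = {v: 0.0 for v in graph.nodes}
    edge_bc = {e: 0.0 for e in graph.edges}
    for s in graph.nodes:
        # single-source shortest-path DAG by BFS
        pred: dict[str, list[str]] = {v: [] for v in graph.nodes}
        sigma = {v: 0.0 for v in graph.nodes}
        dist = {v: -1 for v in graph.nodes}
        sigma[s] = 1.0
        dist[s] = 0
        order: list[str] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # dependency accumulation in reverse BFS order
        delta = {v: 0.0 for v in graph.nodes}
        for w in reversed(order):
            for v in pred[w]:
                c = sigma[v] / sigma[w] * (1.0 + delta[w])
                delta[v] += c
                edge_bc[graph.edge_key(v, w)] += c
            if w != s:
                node_bc[w] += delta[w]
    if not graph.directed:
        for v in node_bc:
            node_bc[v] /= 2.0
        for e in edge_bc:
            edge_bc[e] /= 2.0
    return node_bc, edge_bc


def _node_norm_divisor(n: int, directed: bool) -> float:
    return float((n - 1) * (n - 2)) if directed else (n - 1) * (n - 2) / 2.0


def node_betweenness(graph: BinaryGraph, normalized: bool = True) -> CentralityTable:
    """Node betweenness for every node of ``graph``.

    Normalized scores divide the raw sums by the number of eligible pairs,
    using the whole graph's node count even when components are smaller.
    """
    if graph.n_nodes == 0:
        raise ValueError("betweenness is undefined on an empty graph")
    node_bc, edge_bc = _brandes(graph)
    if normalized:
        if graph.n_nodes < 3:
            logger.warning(
                "normalization undefined for n=%d < 3; scores are all zero",
                graph.n_nodes,
            )
            node_bc = {v: 0.0 for v in node_bc}
        else:
            div = _node_norm_divisor(graph.n_nodes, graph.directed)
            node_bc = {v: bc / div for v, bc in node_bc.items()}
    return CentralityTable(
        node_scores=node_bc,
        edge_scores=edge_bc,
        normalized=normalized,
        directed=graph.directed,
        n_nodes=graph.n_nodes,
        labels={k: n.label for k, n in graph.nodes.items()},
    )


def edge_betweenness(graph: BinaryGraph) -> CentralityTable:
    """Raw edge betweenness (the ranking basis for the primary pathway)."""
    if graph.n_nodes == 0:
        raise ValueError("betweenness is undefined on an empty graph")
    node_bc, edge_bc = _brandes(graph)
    return CentralityTable(
        node_scores=node_bc,
        edge_scores=edge_bc,
        normalized=False,
        directed=graph.directed,
        n_nodes=graph.n_nodes,
        labels={k: n.label for k, n in graph.nodes.items()},
    )


def _all_shortest_paths(
    adj: dict[str, list[str]], s: str, t: str
) -> list[list[str]]:
    """Every shortest s→t path, by BFS layering then DAG backtracking."""
    dist = {s: 0}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    if t not in dist:
        return []
    paths: list[list[str]] = []

    def _extend(path: list[str]) -> None:
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        for w in adj[v]:
            if dist.get(w) == dist[v] + 1 and dist[w] <= dist[t]:
                path.append(w)
                _extend(path)
                path.pop()

    _extend([s])
    return paths


def brute_force_betweenness(graph: BinaryGraph) -> CentralityTable:
    """Oracle: raw betweenness by explicit enumeration of all shortest paths.

    Only intended for tests; refuses graphs above
    :data:`BRUTE_FORCE_MAX_NODES` nodes because path enumeration is
    exponential in the worst case.
    """
    if graph.n_nodes > BRUTE_FORCE_MAX_NODES:
        raise ValueError(
            f"brute-force oracle refuses graphs with more than "
            f"{BRUTE_FORCE_MAX_NODES} nodes (got {graph.n_nodes})"
        )
    if graph.n_nodes == 0:
        raise ValueError("betweenness is undefined on an empty graph")
    adj = graph.neighbors()
    node_bc = {v: 0.0 for v in graph.nodes}
    edge_bc = {e: 0.0 for e in graph.edges}
    keys = sorted(graph.nodes)
    pairs = (
        itertools.permutations(keys, 2)
        if graph.directed
        else itertools.combinations(keys, 2)
    )
    for s, t in pairs:
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        sigma = float(len(paths))
        for path in paths:
            for v in path[1:-1]:
                node_bc[v] += 1.0 / sigma
            for u, w in zip(path, path[1:]):
                edge_bc[graph.edge_key(u, w)] += 1.0 / sigma
    return CentralityTable(
        node_scores=node_bc,
        edge_scores=edge_bc,
        normalized=False,
        directed=graph.directed,
        n_nodes=graph.n_nodes,
        labels={k: n.label for k, n in graph.nodes.items()},
    )


def write_node_centrality_tsv(
    table: CentralityTable, graph: BinaryGraph, path: str | Path
) -> None:
    """Ranked per-node TSV: rank, label, raw score, normalized score."""
    node_raw, _ = _brandes(graph)
    div = (
        _node_norm_divisor(graph.n_nodes, graph.directed)
        if graph.n_nodes >= 3
        else float("nan")
    )
    rows = sorted(
        node_raw.items(), key=lambda kv: (-kv[1], graph.label_of(kv[0]), kv[0])
    )
    lines = ["rank\tnode\traw\tnormalized"]
    for rank, (key, raw) in enumerate(rows, start=1):
        norm = raw / div if div == div and div > 0 else 0.0
        lines.append(f"{rank}\t{graph.label_of(key)}\t{raw:.10g}\t{norm:.10g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_edge_centrality_tsv(
    table: CentralityTable, graph: BinaryGraph, path: str | Path
) -> None:
    """Ranked per-edge TSV: rank, source, target, raw score."""
    rows = sorted(
        table.edge_scores.items(),
        key=lambda kv: (-kv[1], graph.edge_labels(kv[0])),
    )
    lines = ["rank\tsource\ttarget\traw"]
    for rank, (key, raw) in enumerate(rows, start=1):
        a, b = graph.edge_labels(key)
        lines.append(f"{rank}\t{a}\t{b}\t{raw:.10g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
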