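"""Derived networks: the top-k "primary pathway" and seed neighborhoods.

Two extractions are supported.  The primary pathway is the sub-network
formed by the k edges of highest edge betweenness (k defaults to 50).  A
seed neighborhood is the induced subgraph over every node within a given
hop distance of at least one named seed (defaults: two hops from
"Ceramide" and "Inflammation"); hop distance is always measured on the
undirected skeleton so that "within two hops" is symmetric.  Rankings
inside an extracted sub-network are recomputed from scratch on the induced
graph, not inherited from the parent.
"""

from __future__ import annotations

import difflib
from collections import deque
from dataclasses import dataclass, field

from .binarize import BinaryGraph, normalize_label
from .centrality import CentralityTable, edge_betweenness

DEFAULT_K = 50
DEFAULT_SEEDS = ("Ceramide", "Inflammation")
DEFAULT_HOPS = 2

TIE_RULE = "score desc, then lexicographic (source label, target label)"


@dataclass(frozen=True)
class EdgeRanking:
    """Top edges in non-increasing score order with a deterministic tie rule."""

    entries: tuple[tuple[tuple[str, str], float], ...]
    k: int
    tie_rule: str = TIE_RULE

    def __len__(self) -> int:
        return len(self.entries)

    def edges(self) -> list[tuple[str, str]]:
        return [edge for edge, _ in self.entries]


@dataclass
class Subnetwork:
    """An induced sub-network around seed nodes."""

    graph: BinaryGraph
    seeds: list[str]
    hops: int
    provenance: str = ""


def top_k_edges(table: CentralityTable, k: int = DEFAULT_K) -> EdgeRanking:
    """The k highest-scoring edges of a centrality table.

    Ties are broken by lexicographic order of the edge's display labels so
    that equal-score prefixes are reproducible across runs.
    """
    if k <= 0:
        raise ValueError(f"k must be positive (got {k})")
    if not table.edge_scores:
        raise ValueError("centrality table carries no edge scores")

    def sort_key(item: tuple[tuple[str, str], float]):
        (u, v), score = item
        lu, lv = table.labels.get(u, u), table.labels.get(v, v)
        if not table.directed and lu > lv:
            lu, lv = lv, lu
        return (-score, lu, lv, u, v)

    ordered = sorted(table.edge_scores.items(), key=sort_key)
    return EdgeRanking(entries=tuple(ordered[:k]), k=k)


def resolve_seed(graph: BinaryGraph, label: str, *, by_id: bool = False) -> str:
    """Resolve a seed label to exactly one node key.

    Matching is case-insensitive after whitespace normalization (or exact
    on node keys with ``by_id=True``).  Unresolvable labels raise with
    near-miss suggestions; ambiguous labels raise listing every match.
    """
    if by_id:
        if label in graph.nodes:
            return label
        raise KeyError(f"no node with key {label!r}")
    wanted = normalize_label(label)
    matches = [
        key for key, node in graph.nodes.items() if normalize_label(node.label) == wanted
    ]
    if len(matches) == 1:
        return matches[0]
    if not matches:
        candidates = sorted({node.label for node in graph.nodes.values()})
        near = difflib.get_close_matches(label, candidates, n=5, cutoff=0.6)
        hint = f"; did you mean {near}?" if near else ""
        raise KeyError(f"no node labelled {label!r}{hint}")
    raise KeyError(
        f"seed label {label!r} is ambiguous; matches node keys {sorted(matches)}"
    )


def khop_neighborhood(
    graph: BinaryGraph,
    seeds: list[str] | tuple[str, ...] = DEFAULT_SEEDS,
    hops: int = DEFAULT_HOPS,
    *,
    by_id: bool = False,
) -> Subnetwork:
    """Induced subgraph over all nodes within ``hops`` of any seed.

    Distance is undirected regardless of the graph's directedness flag.
    ``hops=0`` keeps only the seeds themselves (and any edges among them).
    """
    if hops < 0:
        raise ValueError(f"hops must be non-negative (got {hops})")
    seed_keys = [resolve_seed(graph, s, by_id=by_id) for s in seeds]
    adj = graph.undirected_neighbors()
    dist: dict[str, int] = {}
    queue: deque[str] = deque()
    for key in seed_keys:
        dist[key] = 0
        queue.append(key)
    while queue:
        v = queue.popleft()
        if dist[v] == hops:
            continue
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    sub = graph.induced_subgraph(dist.keys())
    return Subnetwork(
        graph=sub,
        seeds=[graph.label_of(k) for k in seed_keys],
        hops=hops,
        provenance=f"{hops}-hop neighborhood of {sorted(seeds)}",
    )


def rerank_subnetwork(sub: Subnetwork, k: int = DEFAULT_K) -> EdgeRanking:
    """Top-k edges by betweenness recomputed on the sub-network alone."""
    if sub.graph.n_nodes == 0:
        raise ValueError("subnetwork is empty")
    table = edge_betweenness(sub.graph)
    return top_k_edges(table, k)


def ranking_to_rows(ranking: EdgeRanking, graph: BinaryGraph) -> list[tuple[int, str, str, float]]:
    """Flatten a ranking into (rank, source label, target label, score) rows."""
    rows = []
    for rank, (edge, score) in enumerate(ranking.entries, start=1):
        a, b = graph.edge_labels(edge)
        rows.append((rank, a, b, score))
    return rows


def write_ranking_tsv(ranking: EdgeRanking, graph: BinaryGraph, path) -> None:
    from pathlib import Path

    lines = ["rank\tsource\ttarget\tscore"]
    for rank, a, b, score in ranking_to_rows(ranking, graph):
        lines.append(f"{rank}\t{a}\t{b}\t{score:.10g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
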