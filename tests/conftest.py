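"""Shared fixtures and graph-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from pathcent.binarize import BinaryGraph, BinaryRelation, Node, RelationRule
from pathcent.model import (
    MoleculeClass,
    PathwayMap,
    Reaction,
    ReactionType,
    Species,
)


def graph_from_edges(
    edges: list[tuple[str, str]], *, directed: bool = False, nodes: list[str] | None = None
) -> BinaryGraph:
    """Build a BinaryGraph straight from an edge list (all nodes PROTEIN)."""
    graph = BinaryGraph(directed=directed)
    names = set(nodes or [])
    for u, v in edges:
        names.update((u, v))
    for name in sorted(names):
        graph.add_node(Node(key=name, label=name, molecule_class=MoleculeClass.PROTEIN, member_ids=(name,)))
    for i, (u, v) in enumerate(edges):
        graph.add_relation(
            u, v, BinaryRelation(u, v, RelationRule.REACTANT_PRODUCT, f"r{i}")
        )
    return graph


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4) -> BinaryGraph:
    """Erdős–Rényi-style simple graph over n labelled nodes."""
    names = [f"n{i:02d}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return graph_from_edges(edges, nodes=names)


def to_networkx(graph: BinaryGraph):
    """Convert to a networkx graph (cross-check oracle only)."""
    import networkx as nx

    g = nx.DiGraph() if graph.directed else nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    return g


@pytest.fixture
def tiny_map() -> PathwayMap:
    """Two proteins A, B; phenotype P; ion Ca; one reaction each flavour."""
    species = [
        Species("s1", "A", MoleculeClass.PROTEIN),
        Species("s2", "B", MoleculeClass.PROTEIN),
        Species("s3", "P", MoleculeClass.PHENOTYPE),
        Species("s4", "Ca2+", MoleculeClass.ION),
        Species("s5", "M", MoleculeClass.SIMPLE_MOLECULE),
    ]
    reactions = [
        Reaction("r1", ReactionType.STATE_TRANSITION, ("s1",), ("s2",), ("s5",)),
        Reaction("r2", ReactionType.STATE_TRANSITION, ("s2",), ("s3",)),
        Reaction("r3", ReactionType.TRANSPORT, ("s4",), ("s1",)),
    ]
    return PathwayMap(species=species, reactions=reactions, source_name="tiny")
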