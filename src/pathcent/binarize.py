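"""Decompose process-description reactions into a binary-relation graph.

A process-description reaction links reactant, product and modifier species
through a reaction node.  The binary-relation view flattens each reaction
into pairwise relations: one reactant→product relation per (reactant,
product) pair and one modifier→product relation per (modifier, product)
pair.  The resulting graph is simplified before any centrality analysis:

* only species of the allowed molecule classes are kept (by default
  proteins, complexes, genes, RNAs, simple molecules and phenotypes — ions
  and degraded products are dropped);
* self-loops are removed (they never lie on a shortest path);
* parallel relations between the same node pair collapse into a single
  edge that remembers every supporting relation and origin reaction.

Node identity defaults to merging same-named species across compartments
(a transported metabolite is one biological entity); set
``merge_by_name=False`` to key nodes on SBML species ids instead.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import (
    DEFAULT_ALLOWED_CLASSES,
    MoleculeClass,
    PathwayMap,
    Reaction,
)

logger = logging.getLogger(__name__)


class RelationRule(enum.Enum):
    REACTANT_PRODUCT = "REACTANT_PRODUCT"
    MODIFIER_PRODUCT = "MODIFIER_PRODUCT"


@dataclass(frozen=True)
class BinaryRelation:
    """One decomposed source→target pair with its provenance."""

    source: str
    target: str
    rule: RelationRule
    origin_reaction: str

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target


def decompose_reaction(reaction: Reaction) -> list[BinaryRelation]:
    """Flatten one reaction into binary relations.

    Emits one REACTANT_PRODUCT relation per (reactant, product) pair and
    one MODIFIER_PRODUCT relation per (modifier, product) pair, in role
    order then input order.  A reversible reaction additionally yields the
    reversed (product, reactant) pairs; modifier relations are not
    reversed, since modification acts on the process, not backwards.
    """
    if not reaction.products:
        logger.warning("reaction %s has no products; no relations", reaction.id)
        return []
    out: list[BinaryRelation] = []
    for r in reaction.reactants:
        for p in reaction.products:
            out.append(
                BinaryRelation(r, p, RelationRule.REACTANT_PRODUCT, reaction.id)
            )
    for m in reaction.modifiers:
        for p in reaction.products:
            out.append(
                BinaryRelation(m, p, RelationRule.MODIFIER_PRODUCT, reaction.id)
            )
    if reaction.reversible:
        for p in reaction.products:
            for r in reaction.reactants:
                out.append(
                    BinaryRelation(p, r, RelationRule.REACTANT_PRODUCT, reaction.id)
                )
    return out


@dataclass(frozen=True)
class Node:
    """A graph node: one species, or several same-named species merged."""

    key: str
    label: str
    molecule_class: MoleculeClass
    member_ids: tuple[str, ...]


@dataclass
class EdgeData:
    """Provenance carried by one deduplicated edge."""

    rules: set[RelationRule] = field(default_factory=set)
    origins: set[str] = field(default_factory=set)


def normalize_label(label: str) -> str:
    """Whitespace-normalized, case-folded form used for name matching."""
    return " ".join(label.split()).casefold()


@dataclass
class BinaryGraph:
    """Simple (loop-free, parallel-free) binary-relation graph.

    Edges are keyed by node-key pairs: ordered ``(source, target)`` when
    directed, canonically sorted when undirected.
    """

    directed: bool
    nodes: dict[str, Node] = field(default_factory=dict)
    edges: dict[tuple[str, str], EdgeData] = field(default_factory=dict)

    def edge_key(self, u: str, v: str) -> tuple[str, str]:
        if self.directed:
            return (u, v)
        return (u, v) if u <= v else (v, u)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self) -> dict[str, list[str]]:
        """Out-adjacency (directed) or adjacency (undirected), sorted."""
        adj: dict[str, set[str]] = {k: set() for k in self.nodes}
        for (u, v) in self.edges:
            adj[u].add(v)
            if not self.directed:
                adj[v].add(u)
        return {k: sorted(vs) for k, vs in adj.items()}

    def undirected_neighbors(self) -> dict[str, list[str]]:
        """Adjacency of the undirected skeleton (used for hop distances)."""
        adj: dict[str, set[str]] = {k: set() for k in self.nodes}
        for (u, v) in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return {k: sorted(vs) for k, vs in adj.items()}

    def label_of(self, key: str) -> str:
        return self.nodes[key].label

    def edge_labels(self, key: tuple[str, str]) -> tuple[str, str]:
        """Display labels of an edge, sorted when undirected."""
        a, b = self.label_of(key[0]), self.label_of(key[1])
        if self.directed:
            return (a, b)
        return (a, b) if a <= b else (b, a)

    def add_node(self, node: Node) -> None:
        self.nodes[node.key] = node

    def add_relation(self, u: str, v: str, relation: BinaryRelation) -> None:
        if u not in self.nodes or v not in self.nodes:
            raise KeyError("edge endpoints must be existing nodes")
        if u == v:
            raise ValueError("self-loops are not allowed in a BinaryGraph")
        data = self.edges.setdefault(self.edge_key(u, v), EdgeData())
        data.rules.add(relation.rule)
        data.origins.add(relation.origin_reaction)

    def induced_subgraph(self, keys: Iterable[str]) -> "BinaryGraph":
        keep = set(keys)
        unknown = keep - set(self.nodes)
        if unknown:
            raise KeyError(f"unknown node keys: {sorted(unknown)}")
        sub = BinaryGraph(directed=self.directed)
        for k in sorted(keep):
            sub.add_node(self.nodes[k])
        for (u, v), data in self.edges.items():
            if u in keep and v in keep:
                sub.edges[(u, v)] = EdgeData(set(data.rules), set(data.origins))
        return sub


def build_binary_graph(
    pathway_map: PathwayMap,
    allowed_classes: Iterable[MoleculeClass] = DEFAULT_ALLOWED_CLASSES,
    *,
    directed: bool = False,
    merge_by_name: bool = True,
    include_isolated: bool = False,
) -> BinaryGraph:
    """Assemble the type-filtered, deduplicated binary-relation graph.

    Relations touching a species outside ``allowed_classes`` are dropped,
    as are self-loops (including loops created by name merging, e.g. a
    transport of one species between compartments).  By default only
    species participating in at least one surviving relation become nodes;
    ``include_isolated=True`` also adds isolated allowed-class species.
    """
    allowed = frozenset(allowed_classes)
    if not allowed:
        raise ValueError("allowed_classes must not be empty")

    by_id = pathway_map.species_by_id
    key_of: dict[str, str] = {}
    proto_nodes: dict[str, Node] = {}
    for sp in pathway_map.species:
        if sp.molecule_class not in allowed:
            continue
        key = normalize_label(sp.name) if merge_by_name else sp.id
        key_of[sp.id] = key
        if key in proto_nodes:
            prev = proto_nodes[key]
            if prev.molecule_class is not sp.molecule_class:
                logger.warning(
                    "merged node %r mixes classes %s and %s; keeping %s",
                    prev.label,
                    prev.molecule_class.value,
                    sp.molecule_class.value,
                    prev.molecule_class.value,
                )
            proto_nodes[key] = Node(
                key=key,
                label=prev.label,
                molecule_class=prev.molecule_class,
                member_ids=prev.member_ids + (sp.id,),
            )
        else:
            proto_nodes[key] = Node(
                key=key,
                label=sp.name,
                molecule_class=sp.molecule_class,
                member_ids=(sp.id,),
            )

    graph = BinaryGraph(directed=directed)
    surviving: list[tuple[str, str, BinaryRelation]] = []
    used_keys: set[str] = set()
    n_dropped_class = n_dropped_loop = 0
    for rxn in pathway_map.reactions:
        for rel in decompose_reaction(rxn):
            if rel.source not in key_of or rel.target not in key_of:
                n_dropped_class += 1
                continue
            u, v = key_of[rel.source], key_of[rel.target]
            if u == v:
                n_dropped_loop += 1
                continue
            surviving.append((u, v, rel))
            used_keys.update((u, v))

    node_keys = set(proto_nodes) if include_isolated else used_keys
    for key in sorted(node_keys):
        graph.add_node(proto_nodes[key])
    for u, v, rel in surviving:
        graph.add_relation(u, v, rel)

    logger.info(
        "binary graph: %d nodes, %d edges (%d relations dropped by class "
        "filter, %d self-loops removed)",
        graph.n_nodes,
        graph.n_edges,
        n_dropped_class,
        n_dropped_loop,
    )
    return graph
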