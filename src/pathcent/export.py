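"""Graph exports: SIF and GraphML.

SIF (simple interaction format) rows are ``source<TAB>interaction<TAB>target``
with the relation rule as the interaction keyword.  GraphML carries node
attributes (name, molecule_class) and edge attributes (rules, origin
reactions) so the network can be opened in Cytoscape-style viewers.  Both
writers are deterministic: nodes and edges are emitted in sorted order.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .binarize import BinaryGraph

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def write_sif(graph: BinaryGraph, path: str | Path) -> None:
    lines = []
    for (u, v), data in sorted(graph.edges.items()):
        rule = "_".join(sorted(r.value for r in data.rules))
        lines.append(f"{graph.label_of(u)}\t{rule}\t{graph.label_of(v)}")
    # isolated nodes appear as bare names so they survive the round trip
    linked = {n for edge in graph.edges for n in edge}
    for key in sorted(set(graph.nodes) - linked):
        lines.append(graph.label_of(key))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_graphml(graph: BinaryGraph, path: str | Path) -> None:
    root = etree.Element(f"{{{GRAPHML_NS}}}graphml", nsmap={None: GRAPHML_NS})
    keys = [
        ("d_name", "node", "name", "string"),
        ("d_class", "node", "molecule_class", "string"),
        ("d_rules", "edge", "rules", "string"),
        ("d_origins", "edge", "origin_reactions", "string"),
    ]
    for kid, domain, name, vtype in keys:
        el = etree.SubElement(root, f"{{{GRAPHML_NS}}}key")
        el.set("id", kid)
        el.set("for", domain)
        el.set("attr.name", name)
        el.set("attr.type", vtype)
    g = etree.SubElement(root, f"{{{GRAPHML_NS}}}graph")
    g.set("id", "G")
    g.set("edgedefault", "directed" if graph.directed else "undirected")
    for key in sorted(graph.nodes):
        node = graph.nodes[key]
        el = etree.SubElement(g, f"{{{GRAPHML_NS}}}node")
        el.set("id", key)
        d = etree.SubElement(el, f"{{{GRAPHML_NS}}}data")
        d.set("key", "d_name")
        d.text = node.label
        d = etree.SubElement(el, f"{{{GRAPHML_NS}}}data")
        d.set("key", "d_class")
        d.text = node.molecule_class.value
    for i, ((u, v), data) in enumerate(sorted(graph.edges.items())):
        el = etree.SubElement(g, f"{{{GRAPHML_NS}}}edge")
        el.set("id", f"e{i}")
        el.set("source", u)
        el.set("target", v)
        d = etree.SubElement(el, f"{{{GRAPHML_NS}}}data")
        d.set("key", "d_rules")
        d.text = ",".join(sorted(r.value for r in data.rules))
        d = etree.SubElement(el, f"{{{GRAPHML_NS}}}data")
        d.set("key", "d_origins")
        d.text = ",".join(sorted(data.origins))
    Path(path).write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )
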