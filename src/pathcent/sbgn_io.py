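"""Read and write CellDesigner-dialect SBML pathway maps.

CellDesigner saves SBGN process-description maps as SBML Level 2 documents
whose species and reactions carry extra annotation elements in the vendor
namespace ``http://www.sbml.org/2001/ns/celldesigner``: each species has a
molecule class (protein, complex, ion, phenotype, ...) and each reaction a
reaction type (state transition, heterodimer association, ...).  The SBML
core elements give the reactant/product/modifier role lists; the annotations
give the typing this pipeline analyses.

Parsing is deliberately tolerant of SBML level-2 version differences (it
matches elements by local name) but strict about the dialect: a document
without the CellDesigner namespace is rejected rather than half-read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

from lxml import etree

from .model import (
    MoleculeClass,
    ParseWarning,
    PathwayMap,
    Reaction,
    ReactionType,
    Species,
    TypeCensus,
    ReactionCensus,
    census_to_rows,
)

logger = logging.getLogger(__name__)

CELLDESIGNER_NS = "http://www.sbml.org/2001/ns/celldesigner"
SBML_L2V4_NS = "http://www.sbml.org/sbml/level2/version4"

#: CellDesigner reaction-type strings that are synonyms of the nine
#: canonical types (CellDesigner writes KNOWN_TRANSITION_OMITTED for what
#: the census calls an omitted transition).
REACTION_TYPE_SYNONYMS: dict[str, ReactionType] = {
    "KNOWN_TRANSITION_OMITTED": ReactionType.OMITTED_TRANSITION,
    "NEGATIVE_INFLUENCE": ReactionType.UNKNOWN_NEGATIVE_INFLUENCE,
}


class SbmlParseError(ValueError):
    """The file is not well-formed XML / not structurally valid SBML."""


class DialectError(ValueError):
    """The file is SBML but lacks the CellDesigner annotation namespace."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _iter_local(parent: etree._Element, name: str):
    for child in parent.iter():
        if _local(child.tag) == name:
            yield child


def _children_local(parent: etree._Element, name: str):
    return [c for c in parent if isinstance(c.tag, str) and _local(c.tag) == name]


def _find_celldesigner_class(element: etree._Element) -> str | None:
    """Extract the CellDesigner class string from a species element."""
    for node in element.iter(f"{{{CELLDESIGNER_NS}}}class"):
        if node.text:
            return node.text.strip()
    return None


def _find_reaction_type(element: etree._Element) -> str | None:
    for node in element.iter(f"{{{CELLDESIGNER_NS}}}reactionType"):
        if node.text:
            return node.text.strip()
    return None


def parse_celldesigner_map(
    path: str | Path,
    *,
    class_map: Mapping[str, MoleculeClass] | None = None,
    reaction_type_map: Mapping[str, ReactionType] | None = None,
) -> PathwayMap:
    """Parse a CellDesigner-dialect SBML file into a :class:`PathwayMap`.

    Parameters
    ----------
    path
        SBML Level 2 file carrying CellDesigner annotations.
    class_map
        Optional mapping from non-canonical CellDesigner class strings
        (e.g. ``ANTISENSE_RNA``) to one of the eight molecule classes.  By
        default such species are excluded with a parse warning.
    reaction_type_map
        Same idea for non-canonical reaction-type strings, on top of the
        built-in synonyms.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    SbmlParseError
        If the XML is malformed (the message names the failure position).
    DialectError
        If no CellDesigner annotations are present.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such SBML file: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SbmlParseError(f"not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SbmlParseError(f"root element is <{_local(root.tag)}>, expected <sbml>")

    has_cd = any(True for _ in root.iter(f"{{{CELLDESIGNER_NS}}}*"))
    if not has_cd:
        raise DialectError(
            "document carries no CellDesigner annotations "
            f"(namespace {CELLDESIGNER_NS}); plain SBML is not supported"
        )

    warnings: list[ParseWarning] = []
    extra_classes = dict(class_map or {})
    rxn_type_lookup: dict[str, ReactionType] = dict(REACTION_TYPE_SYNONYMS)
    rxn_type_lookup.update(reaction_type_map or {})

    species: list[Species] = []
    for sp in _iter_local(root, "species"):
        # listOfIncludedSpecies holds complex components; complexes are kept
        # as single nodes, so only top-level species are read.
        parent = sp.getparent()
        if parent is not None and _local(parent.tag) != "listOfSpecies":
            continue
        sid = sp.get("id")
        if sid is None:
            warnings.append(ParseWarning("no-id", "species without id skipped"))
            continue
        name = sp.get("name") or sid
        cls_str = _find_celldesigner_class(sp)
        if cls_str is None:
            warnings.append(
                ParseWarning("no-class", f"species {sid} has no CellDesigner class")
            )
            continue
        try:
            mclass = MoleculeClass(cls_str)
        except ValueError:
            if cls_str in extra_classes:
                mclass = extra_classes[cls_str]
                warnings.append(
                    ParseWarning(
                        "mapped-class",
                        f"species {sid}: class {cls_str} mapped to {mclass.value}",
                    )
                )
            else:
                warnings.append(
                    ParseWarning(
                        "unknown-class",
                        f"species {sid}: unrecognized class {cls_str}; excluded",
                    )
                )
                continue
        species.append(
            Species(
                id=sid,
                name=name,
                molecule_class=mclass,
                compartment=sp.get("compartment", "default"),
            )
        )

    known_ids = {s.id for s in species}
    reactions: list[Reaction] = []
    for rx in _iter_local(root, "reaction"):
        rid = rx.get("id")
        if rid is None:
            warnings.append(ParseWarning("no-id", "reaction without id skipped"))
            continue
        type_str = _find_reaction_type(rx)
        if type_str is None:
            warnings.append(
                ParseWarning("no-type", f"reaction {rid} has no CellDesigner type")
            )
            continue
        try:
            rtype = ReactionType(type_str)
        except ValueError:
            if type_str in rxn_type_lookup:
                rtype = rxn_type_lookup[type_str]
            else:
                warnings.append(
                    ParseWarning(
                        "unknown-type",
                        f"reaction {rid}: unrecognized type {type_str}; excluded",
                    )
                )
                continue

        def _role(list_name: str, ref_name: str) -> tuple[str, ...]:
            out: list[str] = []
            for lst in _children_local(rx, list_name):
                for ref in _iter_local(lst, ref_name):
                    ref_id = ref.get("species")
                    if ref_id is None:
                        continue
                    if ref_id not in known_ids:
                        warnings.append(
                            ParseWarning(
                                "dangling-ref",
                                f"reaction {rid} references unknown or excluded "
                                f"species {ref_id}; reference dropped",
                            )
                        )
                        continue
                    out.append(ref_id)
            return tuple(out)

        reactants = _role("listOfReactants", "speciesReference")
        products = _role("listOfProducts", "speciesReference")
        modifiers = _role("listOfModifiers", "modifierSpeciesReference")
        if not reactants or not products:
            warnings.append(
                ParseWarning(
                    "empty-role",
                    f"reaction {rid} has an empty "
                    f"{'reactant' if not reactants else 'product'} list",
                )
            )
        reversible = (rx.get("reversible", "true").strip().lower()) == "true"
        reactions.append(
            Reaction(
                id=rid,
                reaction_type=rtype,
                reactants=reactants,
                products=products,
                modifiers=modifiers,
                reversible=reversible,
            )
        )

    for w in warnings:
        logger.warning("%s", w)
    return PathwayMap(
        species=species,
        reactions=reactions,
        source_name=path.name,
        warnings=warnings,
    )


def write_celldesigner_map(pathway_map: PathwayMap, path: str | Path) -> None:
    """Serialize a :class:`PathwayMap` as CellDesigner-dialect SBML L2v4.

    The writer emits exactly the subset of the dialect the parser reads
    (ids, names, compartments, molecule classes, role lists, reaction types,
    reversibility), deterministically, so write→parse round-trips.
    """
    nsmap = {None: SBML_L2V4_NS, "celldesigner": CELLDESIGNER_NS}
    sbml = etree.Element(f"{{{SBML_L2V4_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "2")
    sbml.set("version", "4")
    model = etree.SubElement(sbml, f"{{{SBML_L2V4_NS}}}model")
    model.set("id", pathway_map.source_name or "pathway_map")

    compartments = sorted({s.compartment for s in pathway_map.species}) or ["default"]
    loc = etree.SubElement(model, f"{{{SBML_L2V4_NS}}}listOfCompartments")
    for comp in compartments:
        c = etree.SubElement(loc, f"{{{SBML_L2V4_NS}}}compartment")
        c.set("id", comp)

    los = etree.SubElement(model, f"{{{SBML_L2V4_NS}}}listOfSpecies")
    for sp in pathway_map.species:
        el = etree.SubElement(los, f"{{{SBML_L2V4_NS}}}species")
        el.set("id", sp.id)
        el.set("name", sp.name)
        el.set("compartment", sp.compartment)
        ann = etree.SubElement(el, f"{{{SBML_L2V4_NS}}}annotation")
        ext = etree.SubElement(ann, f"{{{CELLDESIGNER_NS}}}extension")
        ident = etree.SubElement(ext, f"{{{CELLDESIGNER_NS}}}speciesIdentity")
        cls = etree.SubElement(ident, f"{{{CELLDESIGNER_NS}}}class")
        cls.text = sp.molecule_class.value

    lor = etree.SubElement(model, f"{{{SBML_L2V4_NS}}}listOfReactions")
    for rxn in pathway_map.reactions:
        el = etree.SubElement(lor, f"{{{SBML_L2V4_NS}}}reaction")
        el.set("id", rxn.id)
        el.set("reversible", "true" if rxn.reversible else "false")
        ann = etree.SubElement(el, f"{{{SBML_L2V4_NS}}}annotation")
        ext = etree.SubElement(ann, f"{{{CELLDESIGNER_NS}}}extension")
        rt = etree.SubElement(ext, f"{{{CELLDESIGNER_NS}}}reactionType")
        rt.text = rxn.reaction_type.value
        if rxn.reactants:
            lst = etree.SubElement(el, f"{{{SBML_L2V4_NS}}}listOfReactants")
            for sid in rxn.reactants:
                ref = etree.SubElement(lst, f"{{{SBML_L2V4_NS}}}speciesReference")
                ref.set("species", sid)
        if rxn.products:
            lst = etree.SubElement(el, f"{{{SBML_L2V4_NS}}}listOfProducts")
            for sid in rxn.products:
                ref = etree.SubElement(lst, f"{{{SBML_L2V4_NS}}}speciesReference")
                ref.set("species", sid)
        if rxn.modifiers:
            lst = etree.SubElement(el, f"{{{SBML_L2V4_NS}}}listOfModifiers")
            for sid in rxn.modifiers:
                ref = etree.SubElement(
                    lst, f"{{{SBML_L2V4_NS}}}modifierSpeciesReference"
                )
                ref.set("species", sid)

    data = etree.tostring(
        sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    Path(path).write_bytes(data)


def write_census_tsv(census: TypeCensus | ReactionCensus, path: str | Path) -> None:
    """Write a census as a two-column UTF-8 TSV (class, count)."""
    lines = ["class\tcount"]
    lines += [f"{name}\t{count}" for name, count in census_to_rows(census)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
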