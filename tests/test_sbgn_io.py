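"""CellDesigner SBML reading/writing and the descriptive censuses."""

from __future__ import annotations

import pytest

from pathcent.model import (
    MoleculeClass,
    PathwayMap,
    Reaction,
    ReactionType,
    Species,
    census_reactions,
    census_species,
)
from pathcent.sbgn_io import (
    DialectError,
    SbmlParseError,
    parse_celldesigner_map,
    write_celldesigner_map,
    write_census_tsv,
)

MINIMAL_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4"
      xmlns:celldesigner="http://www.sbml.org/2001/ns/celldesigner"
      level="2" version="4">
  <model id="minimal">
    <listOfCompartments><compartment id="default"/></listOfCompartments>
    <listOfSpecies>
      <species id="s1" name="A" compartment="default">
        <annotation><celldesigner:extension>
          <celldesigner:speciesIdentity>
            <celldesigner:class>PROTEIN</celldesigner:class>
          </celldesigner:speciesIdentity>
        </celldesigner:extension></annotation>
      </species>
      <species id="s2" name="P" compartment="default">
        <annotation><celldesigner:extension>
          <celldesigner:speciesIdentity>
            <celldesigner:class>PHENOTYPE</celldesigner:class>
          </celldesigner:speciesIdentity>
        </celldesigner:extension></annotation>
      </species>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="r1" reversible="false">
        <annotation><celldesigner:extension>
          <celldesigner:reactionType>STATE_TRANSITION</celldesigner:reactionType>
        </celldesigner:extension></annotation>
        <listOfReactants><speciesReference species="s1"/></listOfReactants>
        <listOfProducts><speciesReference species="s2"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


@pytest.fixture
def minimal_file(tmp_path):
    path = tmp_path / "minimal.xml"
    path.write_text(MINIMAL_SBML, encoding="utf-8")
    return path


def test_parse_minimal_document(minimal_file):
    pmap = parse_celldesigner_map(minimal_file)
    assert len(pmap.species) == 2
    assert len(pmap.reactions) == 1
    assert pmap.warnings == []
    by_id = pmap.species_by_id
    assert by_id["s1"].molecule_class is MoleculeClass.PROTEIN
    assert by_id["s2"].molecule_class is MoleculeClass.PHENOTYPE
    rxn = pmap.reactions[0]
    assert rxn.reaction_type is ReactionType.STATE_TRANSITION
    assert rxn.reactants == ("s1",) and rxn.products == ("s2",)
    assert not rxn.reversible


def test_parse_is_deterministic(minimal_file):
    a = parse_celldesigner_map(minimal_file)
    b = parse_celldesigner_map(minimal_file)
    assert a.species == b.species and a.reactions == b.reactions


def test_truncated_xml_reports_position(tmp_path):
    path = tmp_path / "broken.xml"
    path.write_text(MINIMAL_SBML[: len(MINIMAL_SBML) // 2], encoding="utf-8")
    with pytest.raises(SbmlParseError, match=r"line \d+"):
        parse_celldesigner_map(path)


def test_missing_file_raises_io_error(tmp_path):
    with pytest.raises(FileNotFoundError):
        parse_celldesigner_map(tmp_path / "nope.xml")


def test_plain_sbml_rejected_naming_namespace(tmp_path):
    plain = MINIMAL_SBML.replace("celldesigner:", "x:").replace(
        "xmlns:celldesigner", "xmlns:x"
    ).replace(
        "http://www.sbml.org/2001/ns/celldesigner", "http://example.org/other"
    )
    path = tmp_path / "plain.xml"
    path.write_text(plain, encoding="utf-8")
    with pytest.raises(DialectError, match="celldesigner"):
        parse_celldesigner_map(path)


def test_unknown_class_warned_and_excluded_or_mapped(tmp_path):
    doc = MINIMAL_SBML.replace(
        "<celldesigner:class>PROTEIN</celldesigner:class>",
        "<celldesigner:class>ANTISENSE_RNA</celldesigner:class>",
    )
    path = tmp_path / "odd.xml"
    path.write_text(doc, encoding="utf-8")
    pmap = parse_celldesigner_map(path)
    # default: excluded with a warning, and the dangling reference is flagged
    assert len(pmap.species) == 1
    codes = {w.code for w in pmap.warnings}
    assert "unknown-class" in codes and "dangling-ref" in codes
    # explicit mapping keeps the species as RNA
    mapped = parse_celldesigner_map(
        path, class_map={"ANTISENSE_RNA": MoleculeClass.RNA}
    )
    assert mapped.species_by_id["s1"].molecule_class is MoleculeClass.RNA


def test_celldesigner_synonym_reaction_type(tmp_path):
    doc = MINIMAL_SBML.replace("STATE_TRANSITION", "KNOWN_TRANSITION_OMITTED")
    path = tmp_path / "syn.xml"
    path.write_text(doc, encoding="utf-8")
    pmap = parse_celldesigner_map(path)
    assert pmap.reactions[0].reaction_type is ReactionType.OMITTED_TRANSITION


def test_write_parse_round_trip(tmp_path):
    species = [
        Species("s1", "amyloid-β", MoleculeClass.PROTEIN, "cytosol"),
        Species("s2", "Ceramide", MoleculeClass.SIMPLE_MOLECULE, "membrane"),
        Species("s3", "Inflammation", MoleculeClass.PHENOTYPE),
        Species("s4", "Ca2+", MoleculeClass.ION),
    ]
    reactions = [
        Reaction(
            "r1",
            ReactionType.HETERODIMER_ASSOCIATION,
            ("s1", "s2"),
            ("s3",),
            ("s4",),
            reversible=True,
        ),
        Reaction("r2", ReactionType.TRANSPORT, ("s2",), ("s1",)),
    ]
    original = PathwayMap(species=species, reactions=reactions, source_name="rt")
    path = tmp_path / "rt.xml"
    write_celldesigner_map(original, path)
    parsed = parse_celldesigner_map(path)
    assert parsed.species == original.species
    assert parsed.reactions == original.reactions
    # byte-level determinism of the writer
    path2 = tmp_path / "rt2.xml"
    write_celldesigner_map(original, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_census_counts_and_totals(tiny_map):
    sc = census_species(tiny_map)
    assert sc.counts[MoleculeClass.PROTEIN] == 2
    assert sc.counts[MoleculeClass.PHENOTYPE] == 1
    assert sc.counts[MoleculeClass.ION] == 1
    assert sc.counts[MoleculeClass.SIMPLE_MOLECULE] == 1
    assert sc.total_species == len(tiny_map.species) == sum(sc.counts.values())
    rc = census_reactions(tiny_map)
    assert rc.counts[ReactionType.STATE_TRANSITION] == 2
    assert rc.counts[ReactionType.TRANSPORT] == 1
    assert rc.total_reactions == 3


def test_census_of_empty_map_is_all_zero():
    sc = census_species(PathwayMap())
    assert sc.total_species == 0 and all(v == 0 for v in sc.counts.values())
    rc = census_reactions(PathwayMap())
    assert rc.total_reactions == 0 and all(v == 0 for v in rc.counts.values())


def test_census_tsv_is_utf8_with_totals(tmp_path, tiny_map):
    out = tmp_path / "census.tsv"
    write_census_tsv(census_species(tiny_map), out)
    lines = out.read_text(encoding="utf-8").splitlines()
    assert lines[0] == "class\tcount"
    assert lines[-1] == "TOTAL\t5"


def test_duplicate_species_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        PathwayMap(
            species=[
                Species("s1", "A", MoleculeClass.PROTEIN),
                Species("s1", "B", MoleculeClass.PROTEIN),
            ]
        )


def test_validate_flags_dangling_reference_and_empty_roles():
    pmap = PathwayMap(
        species=[Species("s1", "A", MoleculeClass.PROTEIN)],
        reactions=[Reaction("r1", ReactionType.STATE_TRANSITION, ("s1",), ())],
    )
    warnings = pmap.validate()
    assert any(w.code == "empty-role" for w in warnings)
    bad = PathwayMap(
        species=[Species("s1", "A", MoleculeClass.PROTEIN)],
        reactions=[Reaction("r1", ReactionType.STATE_TRANSITION, ("s9",), ("s1",))],
    )
    with pytest.raises(ValueError, match="unknown"):
        bad.validate()
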