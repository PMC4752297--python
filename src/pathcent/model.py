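"""Core data model for process-description pathway maps.

A pathway map in SBGN process-description style consists of typed species
(molecules and phenotypes) and typed reactions connecting reactants,
products, and modifiers.  CellDesigner stores this as SBML Level 2 plus a
vendor annotation namespace carrying the molecule class of each species and
the type of each reaction; this module defines the in-memory representation
those files are parsed into.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class MoleculeClass(enum.Enum):
    """The eight molecule classes a disease map distinguishes."""

    PROTEIN = "PROTEIN"
    COMPLEX = "COMPLEX"
    SIMPLE_MOLECULE = "SIMPLE_MOLECULE"
    GENE = "GENE"
    RNA = "RNA"
    ION = "ION"
    DEGRADED = "DEGRADED"
    PHENOTYPE = "PHENOTYPE"


class ReactionType(enum.Enum):
    """The nine process-description reaction types."""

    STATE_TRANSITION = "STATE_TRANSITION"
    TRANSCRIPTION = "TRANSCRIPTION"
    TRANSLATION = "TRANSLATION"
    HETERODIMER_ASSOCIATION = "HETERODIMER_ASSOCIATION"
    DISSOCIATION = "DISSOCIATION"
    TRANSPORT = "TRANSPORT"
    UNKNOWN_TRANSITION = "UNKNOWN_TRANSITION"
    UNKNOWN_NEGATIVE_INFLUENCE = "UNKNOWN_NEGATIVE_INFLUENCE"
    OMITTED_TRANSITION = "OMITTED_TRANSITION"


#: Molecule classes retained when building the binary-relation graph:
#: proteins, complexes, genes, RNAs, simple molecules and phenotypes.
#: Ions and degraded products are excluded.
DEFAULT_ALLOWED_CLASSES: frozenset[MoleculeClass] = frozenset(
    {
        MoleculeClass.PROTEIN,
        MoleculeClass.COMPLEX,
        MoleculeClass.GENE,
        MoleculeClass.RNA,
        MoleculeClass.SIMPLE_MOLECULE,
        MoleculeClass.PHENOTYPE,
    }
)


@dataclass(frozen=True)
class Species:
    """One map species: a molecule or phenotype node.

    ``id`` is the SBML species id (graphical aliases of the same species
    collapse onto it); ``name`` is the display label shown on the map.
    """

    id: str
    name: str
    molecule_class: MoleculeClass
    compartment: str = "default"


@dataclass(frozen=True)
class Reaction:
    """One process-description reaction with its role lists.

    Role lists hold species ids.  ``reversible`` mirrors the SBML flag; a
    reversible reaction also proceeds from products back to reactants.
    """

    id: str
    reaction_type: ReactionType
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    modifiers: tuple[str, ...] = ()
    reversible: bool = False


@dataclass
class ParseWarning:
    """A non-fatal issue met while reading a map (never silently dropped)."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


@dataclass
class PathwayMap:
    """A parsed pathway map: typed species plus typed reactions."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    source_name: str = ""
    warnings: list[ParseWarning] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species ids: {dupes}")

    @property
    def species_by_id(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}

    def validate(self) -> list[ParseWarning]:
        """Check referential integrity; returns (and records) warnings."""
        known = {s.id for s in self.species}
        problems: list[ParseWarning] = []
        for rxn in self.reactions:
            for role, ids in (
                ("reactant", rxn.reactants),
                ("product", rxn.products),
                ("modifier", rxn.modifiers),
            ):
                for sid in ids:
                    if sid not in known:
                        raise ValueError(
                            f"reaction {rxn.id} references unknown {role} "
                            f"species {sid!r}"
                        )
            if not rxn.reactants or not rxn.products:
                problems.append(
                    ParseWarning(
                        "empty-role",
                        f"reaction {rxn.id} has an empty "
                        f"{'reactant' if not rxn.reactants else 'product'} list",
                    )
                )
        self.warnings.extend(problems)
        return problems


@dataclass(frozen=True)
class TypeCensus:
    """Species counts per molecule class."""

    counts: Mapping[MoleculeClass, int]
    total_species: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_species:
            raise ValueError("census counts do not sum to total_species")


@dataclass(frozen=True)
class ReactionCensus:
    """Reaction counts per reaction type."""

    counts: Mapping[ReactionType, int]
    total_reactions: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_reactions:
            raise ValueError("census counts do not sum to total_reactions")


def census_species(pathway_map: PathwayMap) -> TypeCensus:
    """Count species per molecule class (all eight classes always present)."""
    counts: dict[MoleculeClass, int] = {c: 0 for c in MoleculeClass}
    for sp in pathway_map.species:
        counts[sp.molecule_class] += 1
    return TypeCensus(counts=counts, total_species=len(pathway_map.species))


def census_reactions(pathway_map: PathwayMap) -> ReactionCensus:
    """Count reactions per reaction type (all nine types always present)."""
    counts: dict[ReactionType, int] = {t: 0 for t in ReactionType}
    for rxn in pathway_map.reactions:
        counts[rxn.reaction_type] += 1
    return ReactionCensus(counts=counts, total_reactions=len(pathway_map.reactions))


def census_to_rows(census: TypeCensus | ReactionCensus) -> list[tuple[str, int]]:
    """Flatten a census into (class, count) rows in enum order, plus a total."""
    rows = [(key.value, n) for key, n in census.counts.items()]
    total = (
        census.total_species
        if isinstance(census, TypeCensus)
        else census.total_reactions
    )
    rows.append(("TOTAL", total))
    return rows
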