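"""Synthetic CellDesigner-dialect pathway maps with known ground truth.

The generator emits maps with the statistical shape of a curated disease
map — a species population over the eight molecule classes, a reaction
population over the nine process-description types, small per-reaction
arities — plus a ground-truth ledger recording exactly what was drawn, so
every pipeline stage can be tested against known answers without any
external file.

Wiring follows preferential attachment: each participant slot is filled
with probability proportional to 1 + (current degree), giving the
heavy-tailed degree structure typical of curated pathway maps.  Named
"hubs" can be planted with a target degree; the generator keeps recruiting
a hub into reactions until it has at least that many distinct neighbors,
providing ground truth for centrality-recovery tests.  Phenotype species
appear only as products by default, mirroring their role as outcome states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .binarize import decompose_reaction
from .model import (
    MoleculeClass,
    PathwayMap,
    Reaction,
    ReactionType,
    Species,
)
from .sbgn_io import write_celldesigner_map

_CLASS_PREFIX = {
    MoleculeClass.PROTEIN: "PROT",
    MoleculeClass.COMPLEX: "CPLX",
    MoleculeClass.SIMPLE_MOLECULE: "SMOL",
    MoleculeClass.GENE: "GENE",
    MoleculeClass.RNA: "RNA",
    MoleculeClass.ION: "ION",
    MoleculeClass.DEGRADED: "DEGR",
    MoleculeClass.PHENOTYPE: "PHEN",
}

Arity = tuple[int, int, int]  # (n_reactants, n_products, n_modifiers)

#: Default arity mix: 1–3 reactants, 1–2 products, 0–2 modifiers, skewed
#: toward the small arities that dominate curated maps.
DEFAULT_ARITY: tuple[tuple[Arity, float], ...] = (
    ((1, 1, 0), 0.30),
    ((1, 1, 1), 0.20),
    ((2, 1, 0), 0.15),
    ((1, 2, 0), 0.10),
    ((2, 1, 1), 0.10),
    ((3, 1, 0), 0.05),
    ((1, 1, 2), 0.05),
    ((2, 2, 1), 0.03),
    ((3, 2, 2), 0.02),
)

#: Type-specific overrides reflecting the semantics of a few types
#: (an association takes two reactants, a dissociation yields two products).
TYPE_ARITY: dict[ReactionType, tuple[tuple[Arity, float], ...]] = {
    ReactionType.HETERODIMER_ASSOCIATION: (((2, 1, 0), 0.7), ((2, 1, 1), 0.3)),
    ReactionType.DISSOCIATION: (((1, 2, 0), 0.8), ((1, 2, 1), 0.2)),
    ReactionType.TRANSCRIPTION: (((1, 1, 0), 0.6), ((1, 1, 1), 0.4)),
    ReactionType.TRANSLATION: (((1, 1, 0), 0.6), ((1, 1, 1), 0.4)),
    ReactionType.TRANSPORT: (((1, 1, 0), 0.8), ((1, 1, 1), 0.2)),
}


@dataclass(frozen=True)
class HubSpec:
    """A node planted with artificially high degree."""

    label: str
    molecule_class: MoleculeClass = MoleculeClass.PROTEIN
    target_degree: int = 20


@dataclass
class SyntheticMapConfig:
    """Generator settings; also the ground truth recovery tests check against."""

    n_species_per_class: Mapping[MoleculeClass, int]
    n_reactions_per_type: Mapping[ReactionType, int] = field(default_factory=dict)
    arity_distribution: Mapping[ReactionType, Sequence[tuple[Arity, float]]] = field(
        default_factory=dict
    )
    hub_spec: tuple[HubSpec, ...] = ()
    random_seed: int = 0
    phenotypes_as_products_only: bool = True

    def validate(self) -> None:
        for cls, n in self.n_species_per_class.items():
            if n < 0:
                raise ValueError(f"negative species count for {cls}")
        for typ, n in self.n_reactions_per_type.items():
            if n < 0:
                raise ValueError(f"negative reaction count for {typ}")
        n_reactions = sum(self.n_reactions_per_type.values())
        if n_reactions > 0:
            if not any(n >= 2 for n in self.n_species_per_class.values()):
                raise ValueError(
                    "reactions requested but no species class has count >= 2"
                )
            non_phen = sum(
                n
                for cls, n in self.n_species_per_class.items()
                if cls is not MoleculeClass.PHENOTYPE
            )
            if self.phenotypes_as_products_only and non_phen < 1:
                raise ValueError(
                    "reactions requested but no eligible reactant species "
                    "(phenotypes are products only)"
                )
        for hub in self.hub_spec:
            if self.n_species_per_class.get(hub.molecule_class, 0) < 1:
                raise ValueError(
                    f"hub {hub.label!r} needs at least one species of class "
                    f"{hub.molecule_class.value}"
                )


@dataclass
class GroundTruthLedger:
    """Exactly what the generator drew, for recovery tests."""

    species_counts: dict[MoleculeClass, int]
    reaction_counts: dict[ReactionType, int]
    hub_labels: list[str]
    roles: dict[str, tuple[str, tuple[str, ...], tuple[str, ...], tuple[str, ...]]]
    random_seed: int

    def to_json(self) -> str:
        payload = {
            "species_counts": {c.value: n for c, n in self.species_counts.items()},
            "reaction_counts": {t.value: n for t, n in self.reaction_counts.items()},
            "hub_labels": self.hub_labels,
            "roles": {
                rid: {
                    "type": typ,
                    "reactants": list(r),
                    "products": list(p),
                    "modifiers": list(m),
                }
                for rid, (typ, r, p, m) in self.roles.items()
            },
            "random_seed": self.random_seed,
        }
        return json.dumps(payload, indent=2, ensure_ascii=False, sort_keys=True)


def _weighted_sample(
    rng: np.random.Generator,
    pool: list[str],
    weights: dict[str, int],
    k: int,
    exclude: set[str],
) -> list[str]:
    """Draw up to k distinct ids from pool \\ exclude, P(v) ∝ 1 + degree(v)."""
    eligible = [v for v in pool if v not in exclude]
    k = min(k, len(eligible))
    if k == 0:
        return []
    w = np.array([1.0 + weights[v] for v in eligible])
    idx = rng.choice(len(eligible), size=k, replace=False, p=w / w.sum())
    return [eligible[i] for i in sorted(idx)]


def generate_map(config: SyntheticMapConfig) -> tuple[PathwayMap, GroundTruthLedger]:
    """Generate a synthetic pathway map and its ground-truth ledger.

    Identical configs (including the seed) produce identical maps.
    """
    config.validate()
    rng = np.random.default_rng(config.random_seed)

    species: list[Species] = []
    hubs_left = list(config.hub_spec)
    counter = 0
    for cls in MoleculeClass:
        n = config.n_species_per_class.get(cls, 0)
        class_hubs = [h for h in hubs_left if h.molecule_class is cls][:n]
        for i in range(n):
            counter += 1
            sid = f"s{counter}"
            if class_hubs:
                hub = class_hubs.pop(0)
                hubs_left.remove(hub)
                name = hub.label
            else:
                name = f"{_CLASS_PREFIX[cls]}_{counter:04d}"
            species.append(Species(id=sid, name=name, molecule_class=cls))
    if hubs_left:
        raise ValueError(f"could not place hubs: {[h.label for h in hubs_left]}")

    by_name = {sp.name: sp for sp in species}
    phen_ids = {
        sp.id for sp in species if sp.molecule_class is MoleculeClass.PHENOTYPE
    }
    all_ids = [sp.id for sp in species]
    reactant_pool = (
        [i for i in all_ids if i not in phen_ids]
        if config.phenotypes_as_products_only
        else list(all_ids)
    )
    degree: dict[str, int] = {i: 0 for i in all_ids}
    hub_ids = {by_name[h.label].id: h for h in config.hub_spec}
    hub_neighbors: dict[str, set[str]] = {i: set() for i in hub_ids}

    reactions: list[Reaction] = []
    ridx = 0
    for rtype in ReactionType:
        n = config.n_reactions_per_type.get(rtype, 0)
        arity_dist = config.arity_distribution.get(
            rtype, TYPE_ARITY.get(rtype, DEFAULT_ARITY)
        )
        arities = [a for a, _ in arity_dist]
        probs = np.array([w for _, w in arity_dist], dtype=float)
        probs /= probs.sum()
        for _ in range(n):
            ridx += 1
            rid = f"re{ridx}"
            nr, npr, nm = arities[rng.choice(len(arities), p=probs)]
            used: set[str] = set()
            reactants: list[str] = []
            products: list[str] = []
            # recruit one deficient hub per reaction, round-robin by deficit
            deficient = sorted(
                (h for h in hub_ids if len(hub_neighbors[h]) < hub_ids[h].target_degree),
                key=lambda h: (len(hub_neighbors[h]), h),
            )
            if deficient:
                h = deficient[0]
                if h in phen_ids and config.phenotypes_as_products_only:
                    products.append(h)
                else:
                    reactants.append(h)
                used.add(h)
            reactants += _weighted_sample(
                rng, reactant_pool, degree, nr - len(reactants), used
            )
            used.update(reactants)
            products += _weighted_sample(
                rng, all_ids, degree, npr - len(products), used
            )
            used.update(products)
            modifiers = _weighted_sample(rng, reactant_pool, degree, nm, used)
            used.update(modifiers)
            if not reactants or not products:
                # degenerate tiny pools; skip rather than emit invalid roles
                continue
            rxn = Reaction(
                id=rid,
                reaction_type=rtype,
                reactants=tuple(reactants),
                products=tuple(products),
                modifiers=tuple(modifiers),
                reversible=False,
            )
            reactions.append(rxn)
            for v in used:
                degree[v] += 1
            for rel in decompose_reaction(rxn):
                if rel.source in hub_neighbors and rel.source != rel.target:
                    hub_neighbors[rel.source].add(rel.target)
                if rel.target in hub_neighbors and rel.source != rel.target:
                    hub_neighbors[rel.target].add(rel.source)

    pmap = PathwayMap(
        species=species, reactions=reactions, source_name="synthetic_map"
    )
    pmap.validate()
    ledger = GroundTruthLedger(
        species_counts={
            cls: config.n_species_per_class.get(cls, 0) for cls in MoleculeClass
        },
        reaction_counts={t: 0 for t in ReactionType},
        hub_labels=[h.label for h in config.hub_spec],
        roles={
            r.id: (r.reaction_type.value, r.reactants, r.products, r.modifiers)
            for r in reactions
        },
        random_seed=config.random_seed,
    )
    for r in reactions:
        ledger.reaction_counts[r.reaction_type] += 1
    return pmap, ledger


def generate_sbml(
    config: SyntheticMapConfig, path: str | Path
) -> tuple[PathwayMap, GroundTruthLedger]:
    """Generate a map and write it as SBML plus a JSON ledger sidecar."""
    pmap, ledger = generate_map(config)
    path = Path(path)
    write_celldesigner_map(pmap, path)
    path.with_suffix(".ledger.json").write_text(
        ledger.to_json() + "\n", encoding="utf-8"
    )
    return pmap, ledger


def make_alzpathway_like_config(random_seed: int = 0) -> SyntheticMapConfig:
    """A config with the published composition of the AD disease map.

    Species and reaction counts equal the published per-class/per-type
    breakdowns (1,384 molecules + 138 phenotypes; 1,124 reactions over the
    nine types).  Three hubs are planted — "amyloid-β", "Ceramide" and
    "Inflammation" — so the default end-to-end analysis (centrality ranking
    and the two-hop neighborhood of Ceramide and Inflammation) runs on the
    synthetic map just as it would on the real one.
    """
    return SyntheticMapConfig(
        n_species_per_class={
            MoleculeClass.PROTEIN: 721,
            MoleculeClass.COMPLEX: 246,
            MoleculeClass.SIMPLE_MOLECULE: 300,
            MoleculeClass.GENE: 33,
            MoleculeClass.RNA: 37,
            MoleculeClass.ION: 24,
            MoleculeClass.DEGRADED: 23,
            MoleculeClass.PHENOTYPE: 138,
        },
        n_reactions_per_type={
            ReactionType.STATE_TRANSITION: 472,
            ReactionType.TRANSCRIPTION: 22,
            ReactionType.TRANSLATION: 30,
            ReactionType.HETERODIMER_ASSOCIATION: 184,
            ReactionType.DISSOCIATION: 56,
            ReactionType.TRANSPORT: 106,
            ReactionType.UNKNOWN_TRANSITION: 22,
            ReactionType.UNKNOWN_NEGATIVE_INFLUENCE: 6,
            ReactionType.OMITTED_TRANSITION: 226,
        },
        hub_spec=(
            HubSpec("amyloid-β", MoleculeClass.PROTEIN, 60),
            HubSpec("Ceramide", MoleculeClass.SIMPLE_MOLECULE, 45),
            HubSpec("Inflammation", MoleculeClass.PHENOTYPE, 25),
        ),
        random_seed=random_seed,
    )
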