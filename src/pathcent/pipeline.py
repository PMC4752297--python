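"""End-to-end pipeline: parse → census → binarize → rank → extract.

``run_pipeline`` drives every stage with one :class:`RunConfig` and writes
the full artifact set into a run directory, together with a manifest
recording every convention that can change a number (directedness,
normalization, name merging, tie rule, k, seeds, hops) and a digest of the
input, so any run is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .binarize import build_binary_graph
from .centrality import (
    edge_betweenness,
    node_betweenness,
    write_edge_centrality_tsv,
    write_node_centrality_tsv,
)
from .export import write_graphml, write_sif
from .model import (
    DEFAULT_ALLOWED_CLASSES,
    MoleculeClass,
    census_reactions,
    census_species,
)
from .sbgn_io import parse_celldesigner_map, write_census_tsv
from .subnetwork import (
    DEFAULT_HOPS,
    DEFAULT_K,
    DEFAULT_SEEDS,
    TIE_RULE,
    khop_neighborhood,
    rerank_subnetwork,
    top_k_edges,
    write_ranking_tsv,
)
from .synthetic import generate_sbml, make_alzpathway_like_config

logger = logging.getLogger(__name__)

PRESETS = ("alzpathway-like",)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a run depends on.  Defaults mirror the published analysis:

    six allowed molecule classes, undirected shortest paths, normalized
    node scores, top 50 edges, and a two-hop neighborhood around
    "Ceramide" and "Inflammation".
    """

    input_path: str | None = None
    preset: str | None = None  # synthesize instead of reading a file
    allowed_classes: frozenset[MoleculeClass] = DEFAULT_ALLOWED_CLASSES
    directed: bool = False
    normalized: bool = True
    merge_by_name: bool = True
    k: int = DEFAULT_K
    seeds: tuple[str, ...] = DEFAULT_SEEDS
    hops: int = DEFAULT_HOPS
    output_dir: str = "results/run"
    random_seed: int = 0
    overwrite: bool = False

    def to_manifest(self, input_digest: str) -> dict:
        d = dataclasses.asdict(self)
        d["allowed_classes"] = sorted(c.value for c in self.allowed_classes)
        d["seeds"] = list(self.seeds)
        d["tie_rule"] = TIE_RULE
        d["input_digest_sha256"] = input_digest
        d["pathcent_version"] = __version__
        return d


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Raises :class:`StageError` naming the failing stage.  An existing
    non-empty output directory is refused unless ``overwrite`` is set.
    """
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise StageError(
            f"setup: output directory {out} is not empty (pass overwrite=True)"
        )
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: input ---------------------------------------------------
    try:
        if config.preset is not None:
            if config.preset not in PRESETS:
                raise ValueError(f"unknown preset {config.preset!r}; have {PRESETS}")
            cfg = make_alzpathway_like_config(random_seed=config.random_seed)
            input_path = out / "synthetic_map.xml"
            generate_sbml(cfg, input_path)
        elif config.input_path is not None:
            input_path = Path(config.input_path)
        else:
            raise ValueError("either input_path or preset must be given")
        pmap = parse_celldesigner_map(input_path)
    except Exception as exc:
        raise StageError(f"input: {exc}") from exc
    logger.info(
        "parsed %s: %d species, %d reactions, %d warnings",
        input_path,
        len(pmap.species),
        len(pmap.reactions),
        len(pmap.warnings),
    )

    # --- stage: census --------------------------------------------------
    try:
        write_census_tsv(census_species(pmap), out / "census_species.tsv")
        write_census_tsv(census_reactions(pmap), out / "census_reactions.tsv")
    except Exception as exc:
        raise StageError(f"census: {exc}") from exc

    # --- stage: binarize ------------------------------------------------
    try:
        graph = build_binary_graph(
            pmap,
            config.allowed_classes,
            directed=config.directed,
            merge_by_name=config.merge_by_name,
        )
        write_sif(graph, out / "binary_graph.sif")
        write_graphml(graph, out / "binary_graph.graphml")
    except Exception as exc:
        raise StageError(f"binarize: {exc}") from exc

    # --- stage: centrality ----------------------------------------------
    try:
        node_table = node_betweenness(graph, normalized=config.normalized)
        edge_table = edge_betweenness(graph)
        write_node_centrality_tsv(node_table, graph, out / "node_betweenness.tsv")
        write_edge_centrality_tsv(edge_table, graph, out / "edge_betweenness.tsv")
    except Exception as exc:
        raise StageError(f"centrality: {exc}") from exc

    # --- stage: primary pathway -----------------------------------------
    try:
        ranking = top_k_edges(edge_table, config.k)
        write_ranking_tsv(ranking, graph, out / "primary_pathway.tsv")
        primary_nodes = {n for e in ranking.edges() for n in e}
        primary = graph.induced_subgraph(primary_nodes)
        write_sif(primary, out / "primary_pathway.sif")
        write_graphml(primary, out / "primary_pathway.graphml")
    except Exception as exc:
        raise StageError(f"primary-pathway: {exc}") from exc

    # --- stage: subnetwork ----------------------------------------------
    try:
        if config.seeds:
            sub = khop_neighborhood(graph, list(config.seeds), config.hops)
            write_sif(sub.graph, out / "subnetwork.sif")
            write_graphml(sub.graph, out / "subnetwork.graphml")
            reranked = rerank_subnetwork(sub, config.k)
            write_ranking_tsv(reranked, sub.graph, out / "subnetwork_top_edges.tsv")
    except Exception as exc:
        raise StageError(f"subnetwork: {exc}") from exc

    # --- stage: manifest -------------------------------------------------
    manifest = config.to_manifest(_digest(Path(input_path)))
    manifest["n_graph_nodes"] = graph.n_nodes
    manifest["n_graph_edges"] = graph.n_edges
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, ensure_ascii=False, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return out
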