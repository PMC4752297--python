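#!/usr/bin/env python
"""Descriptive census of the map: species per molecule class, reactions per type.

Reads results/analysis/map.xml (or --input) and writes
results/analysis/census_species.tsv and census_reactions.tsv.
"""

import argparse
from pathlib import Path

from pathcent.model import census_reactions, census_species, census_to_rows
from pathcent.sbgn_io import parse_celldesigner_map, write_census_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--input", type=Path, default=Path("results/analysis/map.xml"))
parser.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

pmap = parse_celldesigner_map(args.input)
sc, rc = census_species(pmap), census_reactions(pmap)
args.outdir.mkdir(parents=True, exist_ok=True)
write_census_tsv(sc, args.outdir / "census_species.tsv")
write_census_tsv(rc, args.outdir / "census_reactions.tsv")
for census, title in ((sc, "species by class"), (rc, "reactions by type")):
    print(f"--- {title} ---")
    for name, count in census_to_rows(census):
        print(f"{name:28s} {count}")
if pmap.warnings:
    print(f"({len(pmap.warnings)} parse warnings)")
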