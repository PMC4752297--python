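# Methods

## Problem and model

A curated disease map in SBGN process-description (PD) form is a bipartite
object: typed species (proteins, complexes, simple molecules, genes, RNAs,
ions, degraded products, phenotypes) connected through typed reactions, each
with reactant, product and modifier role lists. Topological questions —
which molecules sit on many signalling routes, which relations carry the
most shortest-path traffic — are asked of a plain graph, so the map is
first flattened to *binary-relation* form: each reaction decomposes into
one reactant→product relation per (reactant, product) pair and one
modifier→product relation per (modifier, product) pair. Reversible
reactions also contribute the reversed reactant–product pairs (a no-op
under the undirected default); modifier relations are never reversed, since
modification acts on the process, not backwards.

Before analysis the graph is simplified:

* **Class filter.** Only proteins, complexes, genes, RNAs, simple molecules
  and phenotypes become nodes; ions and degraded products are excluded.
  Relations touching an excluded species are dropped.
* **Self-loops** are removed — they never lie on a shortest path between
  distinct nodes.
* **Parallel relations** between the same node pair collapse into one edge
  that retains every supporting rule and origin reaction, because
  betweenness on multigraphs has no well-defined edge identity.
* **Node identity.** By default same-named species across compartments
  merge into one node (a transported metabolite is one biological entity;
  its transport reaction then becomes a discarded self-loop). The
  alternative, keying nodes on SBML species ids, is available via
  `merge_by_name=False` and is recorded in every run manifest, since the
  choice changes the numbers.

## Betweenness conventions

Node betweenness is C_B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st over unordered pairs
(undirected default; a `--directed` switch treats relations as arcs), where
σ_st counts shortest s–t paths and endpoints are never intermediates. Edge
betweenness is the same sum with "path uses edge e". Unreachable pairs
contribute zero. Node scores are reported normalized by (n−1)(n−2)/2
(undirected) or (n−1)(n−2) (directed), where n is the whole graph's node
count, including on disconnected graphs — the convention of the common
network toolkits. Edge scores are reported raw because only their ranking
is consumed downstream. The undirected + normalized + merge-by-name
defaults are declared assumptions about the original analysis, not stated
facts; the pipeline exposes each as a flag and records all of them, plus
the tie rule and an input digest, in `manifest.json`.

Both scores are computed by Brandes' single-source accumulation over BFS
shortest-path DAGs (exact, O(n·m) for unweighted graphs), with dependencies
accumulated in double precision and no rounding until presentation. An
independent oracle, `brute_force_betweenness`, enumerates every shortest
path explicitly per pair; it refuses graphs above 15 nodes and exists only
so tests can check the fast path against path counting (and, separately,
against networkx) to 1e−9.

Ties in the top-k edge ranking (k defaults to 50) are broken by
lexicographic order of the edge's display labels, so equal-score prefixes
are stable across runs. Seed neighborhoods retain every node within `hops`
(default 2) of any seed, measured on the undirected skeleton regardless of
the analysis directedness — "within two hops" should be symmetric — and
keep the induced edge set. Seed labels match case-insensitively after
whitespace normalization ("Ceramide", "Inflammation" are the defaults).
Rankings inside an extracted subnetwork are recomputed from scratch on the
induced graph, never filtered from the parent ranking.

## Synthetic maps and what they do (not) show

The generator emits CellDesigner-dialect SBML with configurable counts per
molecule class and reaction type, per-reaction arities drawn from a small
distribution (1–3 reactants, 1–2 products, 0–2 modifiers, skewed to the
small arities that dominate curated maps, with semantic overrides such as
two reactants for an association), and participants drawn with probability
proportional to 1 + current degree. Preferential attachment was chosen
because curated maps publish composition but not topology statistics;
it yields the heavy-tailed degree structure such maps typically show, but
the synthetic topology is *not* validated against any real map — by
design. Phenotypes appear only as products, mirroring their role as
outcome states. Everything is driven by one integer seed; identical
configs regenerate byte-identical files, and a ground-truth ledger records
the exact census, role lists and planted hubs for recovery tests.

Named hubs are planted by recruiting the hub into successive reactions
until it has the requested number of distinct neighbors. The
`alzpathway-like` preset uses the published composition of the AD disease
map (721/246/300/33/37/24/23 molecules by class plus 138 phenotypes; 1,124
reactions across the nine types) and plants three hubs — "amyloid-β"
(degree 60), "Ceramide" (45) and "Inflammation" (25) — so the end-to-end
analysis, including the default two-hop extraction around Ceramide and
Inflammation, exercises the same code path it would on the real map. Hub
degrees are fixed design choices emulating the real map's dominant nodes,
not fitted quantities. Consequently, passing tests on synthetic maps
demonstrate that the pipeline recovers structure *it planted* (census,
hubs, seed connectivity); they say nothing about the biology or the exact
centrality values of the real curated map, which require its SBML file
(place it at `data/alzpathway_sbml_map.xml` to run those checks).

## Numerical and degenerate-input choices

* Normalization with fewer than 3 nodes is undefined; scores are reported
  as all-zero with a warning rather than an error.
* An empty graph is an error for centrality; an empty product list in a
  reaction yields no relations plus a logged warning.
* Unrecognized CellDesigner species classes or reaction types are excluded
  with a collected parse warning by default; an explicit mapping table can
  fold them into the canonical eight classes / nine types instead. Known
  CellDesigner synonyms (`KNOWN_TRANSITION_OMITTED`) are folded in
  automatically.
* Parsing matches SBML elements by local name, so any Level 2 version with
  the CellDesigner annotation namespace is accepted; a document without
  that namespace is rejected outright naming the missing namespace.
* Problem sizes in tests: oracle equivalence uses 200 random graphs of
  4–12 nodes (the brute-force oracle caps at 15); hub recovery uses 20
  maps of 100 species / 120 reactions with one degree-20 hub; the
  end-to-end check runs the full ~1,500-species preset once.

## Known limitations

* Modifier semantics are uniform: catalysis, inhibition and unknown
  modification all become modifier→product relations; sign is provenance
  metadata only, so no signed or Boolean interpretation is possible.
* Weighted or sampled betweenness, and other centralities, are out of
  scope.
* The published totals for the real map are internally inconsistent
  (1,538 species vs 1,384 molecules + 138 phenotypes; 1,127 reactions vs a
  breakdown summing to 1,124). The census reports raw counts and takes no
  side; the synthetic preset uses the per-class/per-type breakdowns.
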