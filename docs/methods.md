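# Methods

## The reconstruction model

The package treats a set of curated pathway files as a directed
bipartite-plus-relations graph. Each KGML *reaction* contributes, for
every catalyzing gene, edges `substrate → gene` and `gene → product`
(so a gene node stands between the metabolites of its reaction, and a
path metabolite → gene → metabolite is one reaction); reversible
reactions additionally contribute the mirrored edges. Each `PPrel` or
`GErel` *relation* contributes one `gene → gene` edge. `PCrel`
(protein–compound) relations become `gene → metabolite` edges, oriented
from the gene side and typed like a product edge, the closest available
semantics. `ECrel` relations (enzyme–enzyme coupling through a shared
compound) contribute nothing: the coupling is already explicit through
the two reactions' compound edges, and adding it would double-count.
`maplink` relations and `map`/`ortholog` entries are parsed but never
become nodes or edges — the network contains only genes and metabolites.

Merging several pathways is set union over nodes and typed edges. Edge
identity is `(source, target, edge_type)`; duplicates collapse and their
provenance (pathway id plus reaction/relation reference) accumulates as a
sorted set, which makes the merge commutative over pathway order and
idempotent under duplicated input — both properties are asserted by
tests. When the same node id carries different display labels in
different files, the lexicographically smallest label is kept, keeping
the result order-independent.

Gene classification is a deterministic partition: a gene attached to at
least one reaction is a *metabolic gene*, even if it also appears in
relations (the reaction role dominates in a metabolite-centric network);
a gene appearing only in relations — or nowhere — is a *signaling gene*.
Group entries expand to their member genes and are not nodes themselves.
A compound appearing as both substrate and product of one reaction
contributes no edges for that reaction (logged): such edges carry no
distance or pruning information. Literal self-loops are likewise dropped.

## The filtering cascade

Stage order is fixed: build → seed distances → distance filter →
annotate (expression, prognosis, biofluid) → expression filter →
structural prune → export.

**Distances.** "Steps away" is interpreted as undirected shortest-path
length to the nearest seed, because nodes on both the substrate and the
product side of a seed enzyme are biologically adjacent to it. Directed
variants (`directed_out`, `directed_in`, `directed_either`) are provided
for sensitivity analysis. Distances are computed once, before any
filtering; the node table reports these pre-prune values, so later
removals never silently change a reported distance. The default cutoff
is 3 steps, the canonical compromise between an oversimplified and an
uninterpretable neighborhood. The cutoff applies to all non-seed nodes,
genes included — restricting it to metabolites would leave arbitrarily
distant enzyme chains in place, defeating the simplification.

**Annotation.** Joins are exact on the canonical namespaced id (an
optional alias table maps symbols to ids); there is no fuzzy matching,
because a silent mis-join is worse than a reported miss. Every call
returns a join report in which matched plus unmatched rows equal the
input row count. Prognosis labelling uses strict inequality
(*p* < α, default 0.001): a gene exactly at the threshold is labelled
`none`, though its p-value is still recorded. Missing annotations stay
absent (never false/zero) and export as empty fields: absence of
evidence is not negative evidence.

**Expression filter.** A gene is expressed iff its value strictly
exceeds the threshold (default 0). Genes without a record are removed
and counted in the log — the conservative reading of "not expressed".
Annotation runs first so that the removal lists in the run report carry
the removed genes' annotations.

**Structural prune.** Two rules: (a) remove nodes with no undirected
path to any seed ("connected to the network" is anchored on the seeds);
(b) remove metabolic genes with fewer than `min_metabolite_neighbors`
(default 2) distinct metabolite neighbors, since a gene touching a
single metabolite cannot represent a complete reaction. Signaling genes
are exempt from (b) but not (a). Removals under one rule can create
violations of the other, so by default the pass iterates to a fixpoint,
making the result independent of processing order (asserted under
shuffled node orderings); a single-pass mode emulates a one-shot manual
filter. Each iteration removes whole violation *sets* computed on the
current graph, so no iteration order is ever observable. A seed
metabolic gene violating (b) while metabolites remain in the network is
a degenerate input and raises an error; when no metabolites remain at
all (e.g. after a `max_steps=0` distance filter) rule (b) is vacuous and
the seeds survive, so a seeds-only run is well defined.

## Exports and determinism

Node rows are sorted by (kind, id), edge rows by (source, target, type),
SIF lines lexicographically; files are UTF-8 with Unix newlines and tab
delimiters. GraphML is written from a canonically ordered copy with all
node attributes as typed keys, seed membership as a boolean attribute,
and provenance flattened to a `pathway:ref;...` string that the reader
splits back, so `read(write(N)) == N` including attributes and seeds.
Two runs on identical inputs are byte-identical, including the JSON run
report (which records only file *names*, not paths, for that reason).

## Synthetic data

`make_toy_fixture()` returns two fixed pathways: a four-reaction cycle
(ornithine → citrulline → argininosuccinate ⇌ arginine → ornithine +
urea, with the carbamoyl-phosphate analog consumed by the first step)
and a five-reaction linear chain whose first three steps are catalyzed
by a single trifunctional gene, mirroring the urea-cycle/pyrimidine-
biosynthesis linkage through carbamoyl phosphate; one relation-only gene
provides a signaling node. One seed per pathway anchors the network the
way CPS1 and CAD anchor the original application. Identifiers are
deliberately fictional (`cpd:CX000`, `hsa:9101`): the fixture claims
structural, not biochemical, fidelity. Its manifest — node/edge counts
after every stage, the distance of every node, the final node list and
the golden export files — was enumerated by hand and is re-derived in
tests by independent brute-force oracles (Floyd–Warshall distances, a
set-expansion reachability/pruning reference) before the pipeline output
is compared byte-for-byte.

The annotation tables mark 2 of the 8 genes unexpressed, carry the
published-style prognosis pattern on the two seeds (favorable at
6.93×10⁻⁵, unfavorable at 1.72×10⁻¹¹) plus one row exactly at the 0.001
boundary, and give urine records for 4 of the 11 metabolites.

`random_pathways`/`random_annotations` generate structurally valid
pathways (1–2 substrates, products and genes per reaction, configurable
reversibility and relation counts, round-robin distribution over several
pathway files to exercise merging) and annotation tables with exact
coverage fractions, under a named `numpy` generator seeded from the
config — no global RNG state. Property checks use networks of roughly
4–25 nodes; at that size the O(n³) brute-force oracle is exact and fast,
and 200-network batteries complete in seconds. What these fixtures do
*not* emulate: real pathway sizes (hundreds of entries), multi-compound
stoichiometry, gene families sharing reactions across organisms, or the
noise and versioning drift of real database exports. Passing tests
therefore certify the graph algebra and the cascade's contracts, not
fidelity to any particular database snapshot — headline counts from the
original application depend on 2019-era database content and are not
reproducible offline.

## Numerical and degenerate-input choices

Distances are integer hop counts; unreachable nodes carry an infinity
sentinel and are always removed by the distance filter. Expression and
prognosis thresholds are strict (`>` and `<` respectively). Booleans
serialize as `true`/`false`; numbers use Python's shortest-repr
formatting, which round-trips exactly. Empty networks export as valid
header-only tables and a valid empty GraphML document. Malformed KGML
fails with the offending line; dangling entry references and unknown
entry kinds or relation types fail validation naming the offender; a
reaction with no substrates or products is rejected outright.

## Known limitations

- No stoichiometry, flux or kinetics: a reaction is only its
  substrate/gene/product adjacency, and hypergraph semantics are
  deliberately flattened.
- Distance is unweighted hop count; no probabilistic propagation.
- The pipeline consumes precomputed prognosis labels and p-values; it
  does not fit survival models.
- Live database download is out of scope; file-based KGML input defines
  correctness.
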