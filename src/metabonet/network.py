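"""Merged, deduplicated metabolite-gene network construction.

One or more parsed pathways are flattened into a single directed graph
whose nodes are metabolites and genes and whose edges encode reaction
participation (metabolite -> catalyzing gene -> product metabolite) and
gene-gene signaling relations.  Genes that catalyze at least one reaction
are classified *metabolic*; genes that appear only in relations are
*signaling*.  The graph is stored as a :class:`networkx.DiGraph`; edge
multiplicity is collapsed, with provenance (which pathway and which
reaction/relation produced the edge) accumulated on merge, so that adding
a duplicate pathway is a no-op on topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import networkx as nx

from .kgml import KeggEntry, Pathway

logger = logging.getLogger(__name__)

NODE_METABOLITE = "metabolite"
NODE_METABOLIC_GENE = "metabolic_gene"
NODE_SIGNALING_GENE = "signaling_gene"
NODE_KINDS = (NODE_METABOLITE, NODE_METABOLIC_GENE, NODE_SIGNALING_GENE)

EDGE_SUBSTRATE_TO_GENE = "substrate_to_gene"
EDGE_GENE_TO_PRODUCT = "gene_to_product"
EDGE_GENE_TO_GENE = "gene_to_gene"
EDGE_TYPES = (EDGE_SUBSTRATE_TO_GENE, EDGE_GENE_TO_PRODUCT, EDGE_GENE_TO_GENE)

#: annotation attribute names that modules annotate/export agree on
ANNOTATION_KEYS = (
    "expression_value",
    "prognosis",
    "prognosis_p",
    "urine_normal",
    "urine_abnormal",
)


class NetworkBuildError(ValueError):
    """Raised for inputs that cannot form a valid network."""


class NetworkSummary(NamedTuple):
    n_metabolites: int
    n_metabolic_genes: int
    n_signaling_genes: int
    n_edges: int

    @property
    def n_nodes(self) -> int:
        return self.n_metabolites + self.n_metabolic_genes + self.n_signaling_genes


@dataclass
class MetaboNetwork:
    """A directed metabolite-gene network anchored on seed genes.

    Node attributes: ``kind`` (one of :data:`NODE_KINDS`), ``label``, plus
    any annotation attributes added later (absent until annotated).
    Edge attributes: ``edge_type`` and ``provenance``, a sorted tuple of
    ``(pathway_id, reaction_or_relation_ref)`` pairs.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    seed_ids: frozenset[str] = frozenset()

    def copy(self) -> "MetaboNetwork":
        return MetaboNetwork(self.graph.copy(), frozenset(self.seed_ids))

    def node_kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def nodes_of_kind(self, kind: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == kind}

    @property
    def gene_ids(self) -> set[str]:
        return {
            n
            for n, d in self.graph.nodes(data=True)
            if d["kind"] in (NODE_METABOLIC_GENE, NODE_SIGNALING_GENE)
        }

    @property
    def metabolite_ids(self) -> set[str]:
        return self.nodes_of_kind(NODE_METABOLITE)

    def undirected_neighbors(self, node_id: str) -> set[str]:
        g = self.graph
        return set(g.predecessors(node_id)) | set(g.successors(node_id))

    def metabolite_neighbor_count(self, node_id: str) -> int:
        """Distinct metabolite neighbors ignoring edge direction."""
        return sum(
            1
            for n in self.undirected_neighbors(node_id)
            if self.node_kind(n) == NODE_METABOLITE
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetaboNetwork):
            return NotImplemented
        return (
            self.seed_ids == other.seed_ids
            and dict(self.graph.nodes(data=True)) == dict(other.graph.nodes(data=True))
            and {(u, v): d for u, v, d in self.graph.edges(data=True)}
            == {(u, v): d for u, v, d in other.graph.edges(data=True)}
        )


def _expand_gene_ids(entry: KeggEntry, emap: dict[int, KeggEntry]) -> list[tuple[str, str]]:
    """Expand an entry to (gene_id, label) pairs; groups expand to members."""
    if entry.kind == "group":
        out: list[tuple[str, str]] = []
        for cid in entry.component_ids:
            out.extend(_expand_gene_ids(emap[cid], emap))
        return out
    if entry.kind != "gene":
        return []
    if len(entry.kegg_ids) == 1:
        return [(entry.kegg_ids[0], entry.label)]
    # multi-gene entries: the shared display label would be ambiguous,
    # so each split node is labelled by its own id
    return [(gid, gid) for gid in entry.kegg_ids]


def _expand_compound_ids(entry: KeggEntry) -> list[tuple[str, str]]:
    if entry.kind != "compound":
        return []
    if len(entry.kegg_ids) == 1:
        return [(entry.kegg_ids[0], entry.label)]
    return [(cid, cid) for cid in entry.kegg_ids]


def build_network(
    pathways: Iterable[Pathway], seed_ids: Iterable[str]
) -> MetaboNetwork:
    """Merge pathways into one deduplicated directed metabolite-gene network.

    For every reaction and each catalyzing gene, edges substrate->gene and
    gene->product are added (mirrored for reversible reactions).  PPrel and
    GErel relations become gene->gene edges; PCrel relations become
    gene->metabolite edges; ECrel and maplink relations produce no edges.
    Duplicate edges are collapsed with merged provenance.  Raises
    :class:`NetworkBuildError` on an empty pathway list or a seed id absent
    from every pathway.
    """
    pathways = list(pathways)
    if not pathways:
        raise NetworkBuildError("at least one pathway is required")
    seed_ids = frozenset(seed_ids)

    # node_id -> kind, node_id -> candidate labels
    kinds: dict[str, str] = {}
    labels: dict[str, set[str]] = {}
    genes_in_reactions: set[str] = set()
    # (source, target, edge_type) -> provenance set
    edges: dict[tuple[str, str, str], set[tuple[str, str]]] = {}

    def note_node(node_id: str, compound: bool, label: str) -> None:
        kind = NODE_METABOLITE if compound else "gene"
        prior = kinds.get(node_id)
        if prior is not None and (prior == NODE_METABOLITE) != compound:
            raise NetworkBuildError(
                f"id {node_id!r} is a compound in one pathway and a gene in another"
            )
        kinds[node_id] = kind
        labels.setdefault(node_id, set()).add(label)

    def add_edge(src: str, dst: str, edge_type: str, prov: tuple[str, str]) -> None:
        if src == dst:
            logger.warning("dropping self-loop edge on %s (%s)", src, prov)
            return
        edges.setdefault((src, dst, edge_type), set()).add(prov)

    for pathway in pathways:
        emap = pathway.entry_map()
        for entry in pathway.entries:
            for cid, lab in _expand_compound_ids(entry):
                note_node(cid, True, lab)
            for gid, lab in _expand_gene_ids(entry, emap):
                note_node(gid, False, lab)

        for reaction in pathway.reactions:
            ref = reaction.names[0] if reaction.names else f"reaction{reaction.reaction_id}"
            prov = (pathway.pathway_id, ref)
            substrates = [
                c for sref in reaction.substrate_refs for c, _ in _expand_compound_ids(emap[sref])
            ]
            products = [
                c for pref in reaction.product_refs for c, _ in _expand_compound_ids(emap[pref])
            ]
            shared = set(substrates) & set(products)
            if shared:
                # a compound on both sides of one reaction carries no
                # distance or pruning information; skip its edges
                logger.warning(
                    "reaction %s in %s has compounds %s as both substrate and "
                    "product; their edges are dropped",
                    ref, pathway.pathway_id, sorted(shared),
                )
                substrates = [c for c in substrates if c not in shared]
                products = [c for c in products if c not in shared]
            gene_nodes = [
                g
                for gref in reaction.gene_refs
                for g, _ in _expand_gene_ids(emap[gref], emap)
            ]
            for gene in gene_nodes:
                genes_in_reactions.add(gene)
                for sub in substrates:
                    add_edge(sub, gene, EDGE_SUBSTRATE_TO_GENE, prov)
                    if reaction.reversible:
                        add_edge(gene, sub, EDGE_GENE_TO_PRODUCT, prov)
                for prod in products:
                    add_edge(gene, prod, EDGE_GENE_TO_PRODUCT, prov)
                    if reaction.reversible:
                        add_edge(prod, gene, EDGE_SUBSTRATE_TO_GENE, prov)

        for relation in pathway.relations:
            prov = (
                pathway.pathway_id,
                f"{relation.relation_type}:{relation.entry1}-{relation.entry2}",
            )
            e1 = emap[relation.entry1]
            e2 = emap[relation.entry2]
            if relation.relation_type in ("PPrel", "GErel"):
                for g1, _ in _expand_gene_ids(e1, emap):
                    for g2, _ in _expand_gene_ids(e2, emap):
                        add_edge(g1, g2, EDGE_GENE_TO_GENE, prov)
            elif relation.relation_type == "PCrel":
                # orient from the gene side regardless of entry order
                gene_side, compound_side = (e1, e2) if e1.kind != "compound" else (e2, e1)
                for g, _ in _expand_gene_ids(gene_side, emap):
                    for c, _ in _expand_compound_ids(compound_side):
                        add_edge(g, c, EDGE_GENE_TO_PRODUCT, prov)
            # ECrel: the coupling compound is already explicit via reaction
            # edges; maplink: pathway cross-references never become edges.

    missing = sorted(s for s in seed_ids if kinds.get(s) != "gene")
    if missing:
        raise NetworkBuildError(
            f"seed gene(s) {', '.join(missing)} not found as genes in any pathway"
        )

    graph = nx.DiGraph()
    for node_id in sorted(kinds):
        if kinds[node_id] == NODE_METABOLITE:
            kind = NODE_METABOLITE
        elif node_id in genes_in_reactions:
            kind = NODE_METABOLIC_GENE
        else:
            kind = NODE_SIGNALING_GENE
        graph.add_node(node_id, kind=kind, label=min(labels[node_id]))
    for (src, dst, edge_type), provs in sorted(edges.items()):
        graph.add_edge(src, dst, edge_type=edge_type, provenance=tuple(sorted(provs)))

    return MetaboNetwork(graph=graph, seed_ids=seed_ids)


def network_summary(network: MetaboNetwork) -> NetworkSummary:
    """Count nodes per kind and edges."""
    counts = {k: 0 for k in NODE_KINDS}
    for _, kind in network.graph.nodes(data="kind"):
        counts[kind] += 1
    return NetworkSummary(
        n_metabolites=counts[NODE_METABOLITE],
        n_metabolic_genes=counts[NODE_METABOLIC_GENE],
        n_signaling_genes=counts[NODE_SIGNALING_GENE],
        n_edges=network.graph.number_of_edges(),
    )
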