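import pytest

from metabonet.kgml import parse_kgml
from metabonet.network import (
    EDGE_GENE_TO_GENE,
    EDGE_GENE_TO_PRODUCT,
    EDGE_SUBSTRATE_TO_GENE,
    NODE_METABOLIC_GENE,
    NODE_METABOLITE,
    NODE_SIGNALING_GENE,
    NetworkBuildError,
    build_network,
    network_summary,
)

from conftest import THREE_NODE_KGML, make_random_network


def test_single_reaction_gives_substrate_gene_product_chain(three_node_network):
    net = three_node_network
    assert net.node_kind("cpd:CS") == NODE_METABOLITE
    assert net.node_kind("cpd:CP") == NODE_METABOLITE
    assert net.node_kind("hsa:1") == NODE_METABOLIC_GENE
    edges = {(u, v, d["edge_type"]) for u, v, d in net.graph.edges(data=True)}
    assert edges == {
        ("cpd:CS", "hsa:1", EDGE_SUBSTRATE_TO_GENE),
        ("hsa:1", "cpd:CP", EDGE_GENE_TO_PRODUCT),
    }


def test_summary_of_three_node_network(three_node_network):
    assert network_summary(three_node_network) == (2, 1, 0, 2)


def test_empty_pathway_list_rejected():
    with pytest.raises(NetworkBuildError):
        build_network([], ["hsa:1"])


def test_missing_seed_named_in_error():
    pw = parse_kgml(THREE_NODE_KGML)
    with pytest.raises(NetworkBuildError, match="hsa:404"):
        build_network([pw], ["hsa:404"])


def test_duplicate_pathway_is_idempotent():
    pw = parse_kgml(THREE_NODE_KGML)
    once = build_network([pw], ["hsa:1"])
    twice = build_network([pw, pw], ["hsa:1"])
    assert once == twice


def test_shared_compound_merges_to_single_node(toy, toy_network):
    _, _, manifest = toy
    # the carbamoyl phosphate analog appears in both pathways exactly once
    assert list(toy_network.graph.nodes).count("cpd:CX000") == 1
    provs = {
        pid
        for _, _, d in toy_network.graph.edges(data=True)
        for pid, _ in d["provenance"]
    }
    assert provs == {"syn00001", "syn00002"}


def test_toy_merge_matches_hand_enumeration(toy, toy_network):
    _, _, manifest = toy
    s = network_summary(toy_network)
    assert (s.n_nodes, s.n_metabolites, s.n_metabolic_genes,
            s.n_signaling_genes, s.n_edges) == manifest["stage_counts"]["build"]


def test_reversible_reaction_mirrors_edges(toy_network):
    # rn:RX003 is reversible: ArgSuccinate <-> Arginine via the lyase
    e = {(u, v) for u, v in toy_network.graph.edges}
    assert {"cpd:CX003", "cpd:CX004"} <= {
        n for n in toy_network.graph.nodes
    }
    assert ("cpd:CX003", "hsa:9103") in e and ("hsa:9103", "cpd:CX003") in e
    assert ("hsa:9103", "cpd:CX004") in e and ("cpd:CX004", "hsa:9103") in e


def test_relation_only_gene_is_signaling(toy_network):
    assert toy_network.node_kind("hsa:9204") == NODE_SIGNALING_GENE
    assert ("hsa:9204", "hsa:9201") in set(toy_network.graph.edges)


MIXED_ROLE_KGML = """\
<pathway name="path:syn00020" title="Gene in reaction and relation">
  <entry id="1" name="cpd:CA" type="compound"><graphics name="A"/></entry>
  <entry id="2" name="cpd:CB" type="compound"><graphics name="B"/></entry>
  <entry id="3" name="hsa:10 hsa:11" type="gene" reaction="rn:R1"><graphics name="multi"/></entry>
  <entry id="4" name="hsa:12" type="gene"><graphics name="S"/></entry>
  <entry id="5" name="g" type="group"><component id="3"/><component id="4"/></entry>
  <reaction id="3" name="rn:R1" type="irreversible">
    <substrate id="1" name="cpd:CA"/>
    <product id="2" name="cpd:CB"/>
  </reaction>
  <relation entry1="4" entry2="3" type="PPrel"><subtype name="activation"/></relation>
  <relation entry1="3" entry2="4" type="ECrel"><subtype name="compound"/></relation>
</pathway>
"""


def test_multi_gene_entry_splits_and_mixed_role_is_metabolic():
    net = build_network([parse_kgml(MIXED_ROLE_KGML)], ["hsa:10"])
    # the two-gene entry yields two gene nodes, both catalyzing the reaction
    assert net.node_kind("hsa:10") == NODE_METABOLIC_GENE
    assert net.node_kind("hsa:11") == NODE_METABOLIC_GENE
    # hsa:12 appears only in relations -> signaling
    assert net.node_kind("hsa:12") == NODE_SIGNALING_GENE
    edges = {(u, v, d["edge_type"]) for u, v, d in net.graph.edges(data=True)}
    # PPrel expands to both target genes; ECrel yields nothing
    assert ("hsa:12", "hsa:10", EDGE_GENE_TO_GENE) in edges
    assert ("hsa:12", "hsa:11", EDGE_GENE_TO_GENE) in edges
    assert not any(
        u.startswith("hsa") and v.startswith("hsa") and u != "hsa:12"
        for u, v, _ in edges
    )


PCREL_KGML = """\
<pathway name="path:syn00021" title="Protein-compound relation">
  <entry id="1" name="cpd:CA" type="compound"><graphics name="A"/></entry>
  <entry id="2" name="hsa:20" type="gene"><graphics name="G"/></entry>
  <relation entry1="1" entry2="2" type="PCrel"><subtype name="binding"/></relation>
</pathway>
"""


def test_pcrel_yields_gene_to_metabolite_edge():
    net = build_network([parse_kgml(PCREL_KGML)], ["hsa:20"])
    edges = {(u, v, d["edge_type"]) for u, v, d in net.graph.edges(data=True)}
    assert edges == {("hsa:20", "cpd:CA", EDGE_GENE_TO_PRODUCT)}


SELF_SUBSTRATE_KGML = """\
<pathway name="path:syn00022" title="Compound on both sides">
  <entry id="1" name="cpd:CA" type="compound"><graphics name="A"/></entry>
  <entry id="2" name="cpd:CB" type="compound"><graphics name="B"/></entry>
  <entry id="3" name="hsa:30" type="gene" reaction="rn:R1"><graphics name="G"/></entry>
  <reaction id="3" name="rn:R1" type="irreversible">
    <substrate id="1" name="cpd:CA"/>
    <substrate id="2" name="cpd:CB"/>
    <product id="1" name="cpd:CA"/>
  </reaction>
</pathway>
"""


def test_compound_on_both_sides_contributes_no_edges():
    net = build_network([parse_kgml(SELF_SUBSTRATE_KGML)], ["hsa:30"])
    edges = {(u, v) for u, v in net.graph.edges}
    assert edges == {("cpd:CB", "hsa:30")}
    assert not any(u == v for u, v in edges)


@pytest.mark.parametrize("case_seed", range(10))
def test_merge_is_commutative_over_pathway_order(case_seed):
    from metabonet import SynthConfig, random_pathways

    cfg = SynthConfig(seed=case_seed, n_pathways=2)
    p1, p2 = random_pathways(cfg)
    genes = sorted(
        {g for p in (p1, p2) for e in p.entries if e.kind == "gene" for g in e.kegg_ids}
    )
    assert build_network([p1, p2], genes[:1]) == build_network([p2, p1], genes[:1])


def test_every_edge_respects_direction_constraint():
    for case_seed in range(20):
        net = make_random_network(case_seed)
        for u, v, d in net.graph.edges(data=True):
            ku, kv = net.node_kind(u), net.node_kind(v)
            if d["edge_type"] == EDGE_SUBSTRATE_TO_GENE:
                assert ku == NODE_METABOLITE and kv != NODE_METABOLITE
            elif d["edge_type"] == EDGE_GENE_TO_PRODUCT:
                assert ku != NODE_METABOLITE and kv == NODE_METABOLITE
            else:
                assert ku != NODE_METABOLITE and kv != NODE_METABOLITE


def test_gene_classification_is_a_partition():
    for case_seed in range(20):
        net = make_random_network(case_seed)
        s = network_summary(net)
        assert s.n_nodes == net.graph.number_of_nodes()
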