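import networkx as nx
import pytest

from metabonet.filters import (
    UNREACHABLE,
    DegenerateNetworkError,
    FilterConfig,
    FilterError,
    compute_seed_distances,
    filter_by_distance,
    filter_unexpressed,
    prune_structure,
)
from metabonet.network import (
    MetaboNetwork,
    NODE_METABOLIC_GENE,
    NODE_METABOLITE,
    NODE_SIGNALING_GENE,
)

from conftest import make_random_network
from helpers_oracle import seed_distances_oracle


def chain_network():
    """seed_G -> m1 -> g2 -> m2, plus an isolated metabolite."""
    g = nx.DiGraph()
    g.add_node("G", kind=NODE_METABOLIC_GENE, label="G")
    g.add_node("m1", kind=NODE_METABOLITE, label="m1")
    g.add_node("g2", kind=NODE_METABOLIC_GENE, label="g2")
    g.add_node("m2", kind=NODE_METABOLITE, label="m2")
    g.add_node("iso", kind=NODE_METABOLITE, label="iso")
    g.add_edge("G", "m1", edge_type="gene_to_product", provenance=())
    g.add_edge("m1", "g2", edge_type="substrate_to_gene", provenance=())
    g.add_edge("g2", "m2", edge_type="gene_to_product", provenance=())
    return MetaboNetwork(graph=g, seed_ids=frozenset({"G"}))


def star_network(private_metabolites: bool):
    """Seed metabolite center with 3 metabolic genes, optionally each
    with one private metabolite."""
    g = nx.DiGraph()
    g.add_node("center", kind=NODE_METABOLITE, label="center")
    for i in range(3):
        gene = f"g{i}"
        g.add_node(gene, kind=NODE_METABOLIC_GENE, label=gene)
        g.add_edge("center", gene, edge_type="substrate_to_gene", provenance=())
        if private_metabolites:
            priv = f"p{i}"
            g.add_node(priv, kind=NODE_METABOLITE, label=priv)
            g.add_edge(gene, priv, edge_type="gene_to_product", provenance=())
    return MetaboNetwork(graph=g, seed_ids=frozenset({"center"}))


def test_chain_distances_match_bruteforce():
    net = chain_network()
    d = compute_seed_distances(net, "undirected")
    assert d.distances == {"G": 0, "m1": 1, "g2": 2, "m2": 3}
    assert d.distances == seed_distances_oracle(net, "undirected")
    assert d["iso"] == UNREACHABLE


def test_seed_distance_is_zero_in_every_mode():
    net = chain_network()
    for mode in ("undirected", "directed_out", "directed_in", "directed_either"):
        assert compute_seed_distances(net, mode)["G"] == 0


def test_directed_modes_differ_on_the_chain():
    net = chain_network()
    assert compute_seed_distances(net, "directed_out")["m2"] == 3
    assert compute_seed_distances(net, "directed_in")["m2"] == UNREACHABLE
    assert compute_seed_distances(net, "directed_either")["m2"] == 3


def test_no_seeds_is_an_error():
    net = chain_network()
    net.seed_ids = frozenset()
    with pytest.raises(FilterError):
        compute_seed_distances(net)


def test_distance_filter_keeps_chain_at_three_steps():
    net = chain_network()
    d = compute_seed_distances(net)
    out = filter_by_distance(net, d, 3)
    assert set(out.graph.nodes) == {"G", "m1", "g2", "m2"}


def test_distance_filter_at_zero_keeps_only_seeds():
    net = chain_network()
    d = compute_seed_distances(net)
    out = filter_by_distance(net, d, 0)
    assert set(out.graph.nodes) == {"G"}
    assert out.graph.number_of_edges() == 0


def test_distance_filter_removes_unreachable_and_is_idempotent():
    net = chain_network()
    d = compute_seed_distances(net)
    out = filter_by_distance(net, d, 5)
    assert "iso" not in out.graph
    assert filter_by_distance(out, d, 5) == out


def test_distance_filter_monotone_in_max_steps():
    for case_seed in range(10):
        net = make_random_network(case_seed)
        d = compute_seed_distances(net)
        prev: set = set()
        for k in range(6):
            kept = set(filter_by_distance(net, d, k).graph.nodes)
            assert prev <= kept
            prev = kept


def test_unexpressed_and_missing_genes_removed():
    net = chain_network()
    out = filter_unexpressed(net, {"G": 5.2, "g2": 0.0}, threshold=0.0)
    # g2 at exactly the threshold is "not expressed"; metabolites stay
    assert set(out.graph.nodes) == {"G", "m1", "m2", "iso"}
    out2 = filter_unexpressed(net, {"G": 5.2}, threshold=0.0)
    assert "g2" not in out2.graph
    assert filter_unexpressed(out, {"G": 5.2}, 0.0) == out


def test_toy_expression_filter_leaves_six_genes(toy, toy_network):
    _, tables, _ = toy
    expr = tables.expression[tables.expression["tissue"] == "hepatocytes"]
    out = filter_unexpressed(toy_network, expr, 0.0)
    assert len(out.gene_ids) == 6


def test_prune_degree_rule_boundary():
    """1 metabolite neighbor -> removed; 2 -> retained."""
    net = star_network(private_metabolites=True)
    out = prune_structure(net, 2, True)
    assert set(out.graph.nodes) == set(net.graph.nodes)

    net1 = star_network(private_metabolites=False)
    out1 = prune_structure(net1, 2, True)
    assert set(out1.graph.nodes) == {"center"}


def test_prune_cascades_disconnection_to_fixpoint():
    # chain: removing g2 (1 metabolite neighbor after m2 loss) must also
    # drop the metabolite it stranded
    g = nx.DiGraph()
    for n, kind in (
        ("seed_m", NODE_METABOLITE), ("g1", NODE_METABOLIC_GENE),
        ("m1", NODE_METABOLITE), ("g2", NODE_METABOLIC_GENE),
    ):
        g.add_node(n, kind=kind, label=n)
    g.add_edge("seed_m", "g1", edge_type="substrate_to_gene", provenance=())
    g.add_edge("g1", "m1", edge_type="gene_to_product", provenance=())
    g.add_edge("m1", "g2", edge_type="substrate_to_gene", provenance=())
    net = MetaboNetwork(graph=g, seed_ids=frozenset({"seed_m"}))
    out = prune_structure(net, 2, True)
    # g2 has one metabolite neighbor -> removed; then g1 also has only
    # 2 neighbors (seed_m, m1) -> kept; m1 still connected via g1
    assert set(out.graph.nodes) == {"seed_m", "g1", "m1"}
    single = prune_structure(net, 2, False)
    assert set(single.graph.nodes) == {"seed_m", "g1", "m1"}


def test_prune_output_order_independent():
    from conftest import shuffled_copy

    for case_seed in range(10):
        net = make_random_network(case_seed)
        try:
            ref = prune_structure(net, 2, True)
        except DegenerateNetworkError:
            continue
        for order_seed in range(3):
            assert prune_structure(shuffled_copy(net, order_seed), 2, True) == ref


def test_degenerate_metabolic_seed_raises():
    g = nx.DiGraph()
    g.add_node("gs", kind=NODE_METABOLIC_GENE, label="gs")
    g.add_node("m", kind=NODE_METABOLITE, label="m")
    g.add_edge("m", "gs", edge_type="substrate_to_gene", provenance=())
    net = MetaboNetwork(graph=g, seed_ids=frozenset({"gs"}))
    with pytest.raises(DegenerateNetworkError, match="gs"):
        prune_structure(net, 2, True)


def test_seed_only_network_survives_prune():
    """With no metabolites left the degree rule is vacuous."""
    g = nx.DiGraph()
    g.add_node("gs", kind=NODE_METABOLIC_GENE, label="gs")
    net = MetaboNetwork(graph=g, seed_ids=frozenset({"gs"}))
    out = prune_structure(net, 2, True)
    assert set(out.graph.nodes) == {"gs"}


def test_signaling_genes_exempt_from_degree_rule():
    g = nx.DiGraph()
    g.add_node("center", kind=NODE_METABOLITE, label="c")
    g.add_node("sig", kind=NODE_SIGNALING_GENE, label="s")
    g.add_node("gm", kind=NODE_METABOLIC_GENE, label="gm")
    g.add_edge("gm", "center", edge_type="gene_to_product", provenance=())
    g.add_edge("sig", "gm", edge_type="gene_to_gene", provenance=())
    net = MetaboNetwork(graph=g, seed_ids=frozenset({"center"}))
    out = prune_structure(net, 1, True)
    assert "sig" in out.graph  # connected, exempt from (b)
    out2 = prune_structure(net, 2, True)
    # gm fails the 2-metabolite rule, stranding sig, which rule (a) removes
    assert set(out2.graph.nodes) == {"center"}


def test_filter_config_validation():
    with pytest.raises(FilterError):
        FilterConfig(max_steps=-1)
    with pytest.raises(FilterError):
        FilterConfig(prognosis_alpha=0.0)
    with pytest.raises(FilterError):
        FilterConfig(distance_mode="sideways")
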