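import dataclasses

import networkx as nx
import numpy as np
import pytest

from metabonet import (
    MetaboNetwork,
    SynthConfig,
    build_network,
    make_toy_fixture,
    parse_kgml,
    random_pathways,
)

THREE_NODE_KGML = """\
<pathway name="path:syn00099" title="One reaction">
  <entry id="1" name="cpd:CS" type="compound"><graphics name="S"/></entry>
  <entry id="2" name="cpd:CP" type="compound"><graphics name="P"/></entry>
  <entry id="3" name="hsa:1" type="gene" reaction="rn:R1"><graphics name="G"/></entry>
  <reaction id="10" name="rn:R1" type="irreversible">
    <substrate id="1" name="cpd:CS"/>
    <product id="2" name="cpd:CP"/>
  </reaction>
</pathway>
"""


@pytest.fixture(scope="session")
def toy():
    """(pathways, annotation tables, hand-enumerated manifest)."""
    return make_toy_fixture()


@pytest.fixture(scope="session")
def toy_network(toy):
    pathways, _, manifest = toy
    return build_network(pathways, manifest["seeds"])


@pytest.fixture()
def three_node_network():
    """S -> G -> P, the smallest reaction network."""
    return build_network([parse_kgml(THREE_NODE_KGML)], ["hsa:1"])


def make_random_network(case_seed: int) -> MetaboNetwork:
    """A seeded random network of at most ~25 nodes with 1-2 seed genes."""
    rng = np.random.default_rng(case_seed)
    n_genes = int(rng.integers(1, 11))
    cfg = SynthConfig(
        n_compounds=int(rng.integers(2, 13)),
        n_genes=n_genes,
        n_reactions=int(rng.integers(1, 11)),
        p_reversible=float(rng.uniform(0, 0.5)),
        n_relations=int(rng.integers(0, 4)) if n_genes >= 2 else 0,
        seed=case_seed,
        n_pathways=int(rng.integers(1, 3)),
    )
    pathways = random_pathways(cfg)
    genes = sorted(
        {g for p in pathways for e in p.entries if e.kind == "gene" for g in e.kegg_ids}
    )
    n_seeds = 1 if len(genes) == 1 else int(rng.integers(1, 3))
    return build_network(pathways, genes[:n_seeds])


def shuffled_copy(network: MetaboNetwork, order_seed: int) -> MetaboNetwork:
    """Same network, different node/edge insertion order."""
    rng = np.random.default_rng(order_seed)
    g = nx.DiGraph()
    nodes = list(network.graph.nodes(data=True))
    edges = list(network.graph.edges(data=True))
    rng.shuffle(nodes)
    rng.shuffle(edges)
    for n, d in nodes:
        g.add_node(n, **d)
    for u, v, d in edges:
        g.add_edge(u, v, **d)
    return MetaboNetwork(graph=g, seed_ids=frozenset(network.seed_ids))
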