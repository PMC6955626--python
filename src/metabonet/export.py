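"""Deterministic exports: node/edge tables, SIF and GraphML.

All writers sort rows and emit UTF-8 with Unix newlines and tab
delimiters, so re-running on the same network is byte-identical
regardless of in-memory ordering — which makes golden-file testing and
run-to-run diffing trivial.  Absent attributes export as empty strings
(not "NA"), which Cytoscape treats as missing.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .filters import DistanceMap, UNREACHABLE
from .network import MetaboNetwork, network_summary

NODE_COLUMNS = (
    "node_id",
    "label",
    "kind",
    "is_seed",
    "distance",
    "expression_value",
    "prognosis",
    "prognosis_p",
    "urine_normal",
    "urine_abnormal",
)

EDGE_COLUMNS = ("source", "target", "edge_type", "provenance")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _write_text(path: str | Path, text: str) -> Path:
    path = Path(path)
    path.write_text(text, encoding="utf-8", newline="\n")
    return path


def node_table_text(network: MetaboNetwork, distances: DistanceMap | None = None) -> str:
    """Render the node table; rows sorted by (kind, node_id)."""
    lines = ["\t".join(NODE_COLUMNS)]
    order = sorted(
        network.graph.nodes(data=True), key=lambda nd: (nd[1]["kind"], nd[0])
    )
    for node_id, data in order:
        if distances is None:
            dist = ""
        else:
            d = distances[node_id]
            dist = "" if d == UNREACHABLE else str(int(d))
        row = (
            node_id,
            data.get("label", node_id),
            data["kind"],
            node_id in network.seed_ids,
            dist,
            data.get("expression_value"),
            data.get("prognosis"),
            data.get("prognosis_p"),
            data.get("urine_normal"),
            data.get("urine_abnormal"),
        )
        lines.append("\t".join(_fmt(v) for v in row))
    return "\n".join(lines) + "\n"


def edge_table_text(network: MetaboNetwork) -> str:
    """Render the edge table; rows sorted by (source, target, edge_type)."""
    lines = ["\t".join(EDGE_COLUMNS)]
    for u, v, data in sorted(
        network.graph.edges(data=True),
        key=lambda e: (e[0], e[1], e[2]["edge_type"]),
    ):
        prov = ";".join(f"{pid}:{ref}" for pid, ref in data.get("provenance", ()))
        lines.append("\t".join((u, v, data["edge_type"], prov)))
    return "\n".join(lines) + "\n"


def sif_text(network: MetaboNetwork) -> str:
    """Render SIF lines ``source<TAB>edge_type<TAB>target``, sorted."""
    lines = sorted(
        f"{u}\t{d['edge_type']}\t{v}" for u, v, d in network.graph.edges(data=True)
    )
    return "\n".join(lines) + ("\n" if lines else "")


def write_node_table(
    network: MetaboNetwork, path: str | Path, distances: DistanceMap | None = None
) -> Path:
    return _write_text(path, node_table_text(network, distances))


def write_edge_table(network: MetaboNetwork, path: str | Path) -> Path:
    return _write_text(path, edge_table_text(network))


def write_sif(network: MetaboNetwork, path: str | Path) -> Path:
    return _write_text(path, sif_text(network))


def _sorted_for_graphml(network: MetaboNetwork) -> nx.DiGraph:
    """A copy with canonical node/edge insertion order and flat attributes."""
    g = nx.DiGraph()
    for node_id, data in sorted(
        network.graph.nodes(data=True), key=lambda nd: (nd[1]["kind"], nd[0])
    ):
        attrs = dict(data)
        attrs["is_seed"] = node_id in network.seed_ids
        g.add_node(node_id, **attrs)
    for u, v, data in sorted(
        network.graph.edges(data=True), key=lambda e: (e[0], e[1], e[2]["edge_type"])
    ):
        prov = ";".join(f"{pid}:{ref}" for pid, ref in data.get("provenance", ()))
        g.add_edge(u, v, edge_type=data["edge_type"], provenance=prov)
    return g


def write_graphml(network: MetaboNetwork, path: str | Path) -> Path:
    """Write GraphML with typed node/edge attributes (plain dialect)."""
    path = Path(path)
    nx.write_graphml(_sorted_for_graphml(network), path, named_key_ids=True)
    return path


def read_graphml(path: str | Path) -> MetaboNetwork:
    """Read a GraphML file written by :func:`write_graphml` back into a network."""
    g = nx.read_graphml(path)
    out = nx.DiGraph()
    seeds = set()
    for node_id, data in g.nodes(data=True):
        attrs = dict(data)
        if attrs.pop("is_seed", False):
            seeds.add(node_id)
        out.add_node(node_id, **attrs)
    for u, v, data in g.edges(data=True):
        prov = tuple(
            tuple(item.split(":", 1)) for item in data.get("provenance", "").split(";") if item
        )
        out.add_edge(u, v, edge_type=data["edge_type"], provenance=prov)
    return MetaboNetwork(graph=out, seed_ids=frozenset(seeds))


def check_table_counts(network: MetaboNetwork) -> None:
    """Assert node/edge table row counts equal the network summary."""
    summary = network_summary(network)
    n_node_rows = node_table_text(network).count("\n") - 1
    n_edge_rows = edge_table_text(network).count("\n") - 1
    assert n_node_rows == summary.n_nodes
    assert n_edge_rows == summary.n_edges
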