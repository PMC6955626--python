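"""The seed-anchored filtering cascade.

Three filters reduce the merged network to its biologically coherent core:

1. *distance filter* — keep nodes within ``max_steps`` edges of the nearest
   seed gene (the simplification step that trims the merged pathways);
2. *expression filter* — drop gene nodes not expressed in the tissue of
   interest (hepatocytes in the original application);
3. *structural prune* — drop nodes disconnected from every seed and
   metabolic genes connected to fewer than ``min_metabolite_neighbors``
   distinct metabolites (a gene touching a single metabolite cannot
   represent a complete substrate->product reaction).

Distances default to the undirected interpretation of "steps away";
directed variants are available for sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .network import (
    MetaboNetwork,
    NODE_METABOLIC_GENE,
    NODE_METABOLITE,
    NODE_SIGNALING_GENE,
)

logger = logging.getLogger(__name__)

#: sentinel distance for nodes with no path to any seed
UNREACHABLE = math.inf

DISTANCE_MODES = ("undirected", "directed_out", "directed_in", "directed_either")


class FilterError(ValueError):
    """Raised for invalid filter inputs."""


class DegenerateNetworkError(FilterError):
    """A metabolic seed gene fails the minimum-metabolite-neighbor rule."""


@dataclass(frozen=True)
class FilterConfig:
    """All thresholds of the filtering cascade.

    max_steps: maximum graph distance from the nearest seed (default 3).
    distance_mode: how "steps away" treats edge direction.
    expression_threshold: a gene is expressed iff value > threshold.
    prognosis_alpha: log-rank p-value cutoff for prognosis labels.
    min_metabolite_neighbors: minimum distinct metabolite neighbors a
        metabolic gene must keep (default 2, one full reaction).
    prune_to_fixpoint: iterate disconnection/degree pruning until stable.
    """

    max_steps: int = 3
    distance_mode: str = "undirected"
    expression_threshold: float = 0.0
    prognosis_alpha: float = 0.001
    min_metabolite_neighbors: int = 2
    prune_to_fixpoint: bool = True

    def __post_init__(self) -> None:
        if self.max_steps < 0:
            raise FilterError("max_steps must be >= 0")
        if self.distance_mode not in DISTANCE_MODES:
            raise FilterError(f"distance_mode must be one of {DISTANCE_MODES}")
        if not 0 < self.prognosis_alpha <= 1:
            raise FilterError("prognosis_alpha must be in (0, 1]")
        if self.expression_threshold < 0:
            raise FilterError("expression_threshold must be >= 0")
        if self.min_metabolite_neighbors < 0:
            raise FilterError("min_metabolite_neighbors must be >= 0")


@dataclass(frozen=True)
class DistanceMap:
    """Minimum number of steps from each node to the nearest seed.

    Unreachable nodes are absent from the mapping and read back as the
    :data:`UNREACHABLE` sentinel.
    """

    distances: dict[str, int]

    def __getitem__(self, node_id: str) -> float:
        return self.distances.get(node_id, UNREACHABLE)

    def get(self, node_id: str, default: float = UNREACHABLE) -> float:
        return self.distances.get(node_id, default)

    def reachable(self) -> set[str]:
        return set(self.distances)


def compute_seed_distances(
    network: MetaboNetwork, mode: str = "undirected"
) -> DistanceMap:
    """Shortest-path step counts from every node to the nearest seed.

    ``undirected`` ignores edge direction; ``directed_out`` follows edges
    away from seeds; ``directed_in`` follows edges toward seeds;
    ``directed_either`` is the minimum of the two directed distances.
    """
    if not network.seed_ids:
        raise FilterError("network has no seed nodes")
    if mode not in DISTANCE_MODES:
        raise FilterError(f"unknown distance mode {mode!r}")
    seeds = set(network.seed_ids)

    def bfs(graph: nx.Graph) -> dict[str, int]:
        dist: dict[str, int] = {}
        for seed in seeds:
            if seed not in graph:
                continue
            for node, d in nx.single_source_shortest_path_length(graph, seed).items():
                if d < dist.get(node, int(1e9)):
                    dist[node] = int(d)
        return dist

    g = network.graph
    if mode == "undirected":
        dist = bfs(g.to_undirected(as_view=True))
    elif mode == "directed_out":
        dist = bfs(g)
    elif mode == "directed_in":
        dist = bfs(g.reverse(copy=False))
    else:  # directed_either
        out = bfs(g)
        inc = bfs(g.reverse(copy=False))
        dist = {
            n: min(out.get(n, UNREACHABLE), inc.get(n, UNREACHABLE))
            for n in set(out) | set(inc)
        }
        dist = {n: int(d) for n, d in dist.items()}
    return DistanceMap(distances=dist)


def _induced(network: MetaboNetwork, keep: set[str]) -> MetaboNetwork:
    graph = network.graph.subgraph(keep).copy()
    return MetaboNetwork(graph=graph, seed_ids=frozenset(network.seed_ids & keep))


def filter_by_distance(
    network: MetaboNetwork, distances: DistanceMap, max_steps: int
) -> MetaboNetwork:
    """Induced subgraph on nodes within ``max_steps`` of a seed.

    Seeds are always retained; unreachable nodes are always removed.
    """
    keep = {
        n for n in network.graph.nodes if distances[n] <= max_steps
    } | set(network.seed_ids)
    return _induced(network, keep)


def filter_unexpressed(
    network: MetaboNetwork,
    expression: Mapping[str, float] | pd.DataFrame,
    threshold: float = 0.0,
) -> MetaboNetwork:
    """Remove gene nodes not expressed above ``threshold``.

    ``expression`` maps gene id -> expression value (a DataFrame with
    ``gene_id``/``value`` columns is accepted).  Genes with no entry are
    treated as not expressed and removed; metabolites are never removed.
    """
    if isinstance(expression, pd.DataFrame):
        expression = dict(zip(expression["gene_id"], expression["value"]))
    missing = sorted(g for g in network.gene_ids if g not in expression)
    if missing:
        logger.info(
            "%d gene node(s) have no expression record and are removed: %s",
            len(missing), ", ".join(missing),
        )
    keep = set(network.metabolite_ids) | {
        g for g in network.gene_ids if float(expression.get(g, 0.0)) > threshold
    }
    return _induced(network, keep)


def prune_structure(
    network: MetaboNetwork,
    min_metabolite_neighbors: int = 2,
    to_fixpoint: bool = True,
) -> MetaboNetwork:
    """Remove seed-disconnected nodes and under-connected metabolic genes.

    Each pass removes (a) every node with no undirected path to any seed,
    then (b) every non-seed metabolic gene with fewer than
    ``min_metabolite_neighbors`` distinct metabolite neighbors (signaling
    genes are exempt from (b)).  With ``to_fixpoint`` the pass repeats until
    nothing changes, so the output satisfies both conditions simultaneously;
    the single-pass mode emulates a manual one-shot filter.

    A *seed* metabolic gene violating (b) while metabolites remain in the
    network is a degenerate input and raises
    :class:`DegenerateNetworkError`; if no metabolites remain (e.g. after a
    ``max_steps=0`` distance filter) the rule is vacuous and seeds are kept.
    """
    if not network.seed_ids & set(network.graph.nodes):
        raise FilterError("network has no seed nodes to prune against")
    current = network.copy()
    while True:
        seeds = set(current.seed_ids)
        undirected = current.graph.to_undirected(as_view=True)
        reachable: set[str] = set()
        for seed in seeds:
            if seed in current.graph:
                reachable |= set(nx.node_connected_component(undirected, seed))
        disconnected = set(current.graph.nodes) - reachable
        if disconnected:
            current = _induced(current, reachable)

        under = {
            g
            for g in current.nodes_of_kind(NODE_METABOLIC_GENE)
            if current.metabolite_neighbor_count(g) < min_metabolite_neighbors
        }
        bad_seeds = under & set(current.seed_ids)
        if bad_seeds:
            if current.metabolite_ids:
                raise DegenerateNetworkError(
                    "seed metabolic gene(s) "
                    + ", ".join(sorted(bad_seeds))
                    + f" have fewer than {min_metabolite_neighbors} metabolite "
                    "neighbors; the seed neighborhood is degenerate"
                )
            under -= bad_seeds
        if under:
            current = _induced(current, set(current.graph.nodes) - under)

        if not (disconnected or under) or not to_fixpoint:
            return current
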