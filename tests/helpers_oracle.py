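"""Independent brute-force oracles used to check the package's graph code.

These deliberately avoid networkx and the package's own traversal code:
shortest paths come from a Floyd-Warshall dynamic program over an
explicit distance matrix, and reachability from naive set expansion.
"""

from __future__ import annotations

INF = float("inf")


def floyd_warshall(nodes: list[str], arcs: set[tuple[str, str]]) -> list[list[float]]:
    """All-pairs shortest hop counts over directed arcs, O(n^3) DP."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = [[INF] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0
    for u, v in arcs:
        dist[idx[u]][idx[v]] = 1
    for k in range(n):
        dk = dist[k]
        for i in range(n):
            dik = dist[i][k]
            if dik == INF:
                continue
            di = dist[i]
            for j in range(n):
                alt = dik + dk[j]
                if alt < di[j]:
                    di[j] = alt
    return dist


def seed_distances_oracle(network, mode: str) -> dict[str, int]:
    """Min hops from the nearest seed to every node, per distance mode."""
    nodes = sorted(network.graph.nodes)
    edges = {(u, v) for u, v in network.graph.edges}
    seeds = sorted(network.seed_ids)

    def one(arcs: set[tuple[str, str]]) -> dict[str, float]:
        dist = floyd_warshall(nodes, arcs)
        idx = {n: i for i, n in enumerate(nodes)}
        return {
            n: min(dist[idx[s]][idx[n]] for s in seeds) for n in nodes
        }

    if mode == "undirected":
        out = one(edges | {(v, u) for u, v in edges})
    elif mode == "directed_out":
        out = one(edges)
    elif mode == "directed_in":
        out = one({(v, u) for u, v in edges})
    elif mode == "directed_either":
        fwd = one(edges)
        bwd = one({(v, u) for u, v in edges})
        out = {n: min(fwd[n], bwd[n]) for n in fwd}
    else:
        raise ValueError(mode)
    return {n: int(d) for n, d in out.items() if d != INF}


def reachable_from_seeds(nodes, edges, seeds) -> set[str]:
    """Undirected reachability by naive set expansion."""
    undirected = set(edges) | {(v, u) for u, v in edges}
    frontier = set(seeds) & set(nodes)
    reached = set(frontier)
    while frontier:
        nxt = {
            v for u, v in undirected if u in frontier and v not in reached
        }
        reached |= nxt
        frontier = nxt
    return reached


def prune_oracle(
    node_kinds: dict[str, str],
    edges: set[tuple[str, str]],
    seeds: set[str],
    min_metabolite_neighbors: int = 2,
) -> set[str]:
    """Reference fixpoint of the disconnection + degree pruning rules."""
    nodes = set(node_kinds)
    while True:
        nodes = reachable_from_seeds(nodes, {
            (u, v) for u, v in edges if u in nodes and v in nodes
        }, seeds)
        live = {(u, v) for u, v in edges if u in nodes and v in nodes}
        under = set()
        for g in nodes:
            if node_kinds[g] != "metabolic_gene" or g in seeds:
                continue
            neigh = {v for u, v in live if u == g} | {u for u, v in live if v == g}
            met = {n for n in neigh if node_kinds[n] == "metabolite"}
            if len(met) < min_metabolite_neighbors:
                under.add(g)
        if not under:
            return nodes
        nodes -= under
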