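"""Brute-force reference implementations.

Everything here is deliberately simple and quadratic-or-worse: exact
all-pairs shortest paths by Dijkstra, exact shortest proper cycles,
transitive-closure reachability, a backward path scan for last2reach,
the ``O(N^2)`` chaining DP under *exact* distances (the shortest-path
gap model), and a linear-scan range maximum.  These are the authorities
the fast implementations are tested against; guards cap the instance
sizes they accept.
"""

from __future__ import annotations

import heapq
from math import inf
from typing import Callable

import networkx as nx

from panchain.chaining import Anchor, AnchorSet, gap_q, precedes
from panchain.graph_io import PangenomeGraph
from panchain.preprocess import PathCover

__all__ = [
    "all_pairs_shortest",
    "cycle_dist_exact",
    "reach_table",
    "last2reach_bruteforce",
    "chain_quadratic_exact",
    "naive_range_max",
]

_MAX_VERTICES = 200
_MAX_ANCHORS = 500


def _guard_graph(g: PangenomeGraph) -> None:
    if g.n_vertices > _MAX_VERTICES:
        raise ValueError(
            f"oracle guard: {g.n_vertices} vertices exceeds {_MAX_VERTICES}"
        )


def all_pairs_shortest(g: PangenomeGraph) -> dict[tuple[str, str], float]:
    """Exact ``D(v1, v2)`` for all ordered pairs; ``inf`` if unreachable.

    Edge ``(v, u)`` has length ``|sigma(v)|``.  Dijkstra with a binary
    heap from every vertex; ties broken by vertex id.  ``D(v, v) = 0``.
    """
    _guard_graph(g)
    D: dict[tuple[str, str], float] = {}
    for s in g.vertices:
        dist: dict[str, float] = {s: 0}
        pq: list[tuple[float, str]] = [(0, s)]
        while pq:
            dv, v = heapq.heappop(pq)
            if dv > dist.get(v, inf):
                continue
            w = dv + g.label_len(v)
            for u in g.out_neighbors(v):
                if w < dist.get(u, inf):
                    dist[u] = w
                    heapq.heappush(pq, (w, u))
        for t in g.vertices:
            D[(s, t)] = dist.get(t, inf)
    return D


def cycle_dist_exact(
    g: PangenomeGraph, D: dict[tuple[str, str], float]
) -> dict[str, float]:
    """Exact shortest proper cycle length through each vertex.

    ``Dcyc(v) = min over u in out-neighbors of |sigma(v)| + D(u, v)``;
    ``inf`` when ``v`` lies on no proper cycle.
    """
    out: dict[str, float] = {}
    for v in g.vertices:
        best = inf
        lv = g.label_len(v)
        for u in g.out_neighbors(v):
            cand = lv + D[(u, v)]
            if cand < best:
                best = cand
        out[v] = best
    return out


def reach_table(g: PangenomeGraph) -> dict[str, set[str]]:
    """``R-(v)``: the set of vertices that reach ``v`` (including ``v``)."""
    _guard_graph(g)
    ng = nx.DiGraph()
    ng.add_nodes_from(g.vertices)
    ng.add_edges_from(g.edges())
    return {v: set(nx.ancestors(ng, v)) | {v} for v in g.vertices}


def last2reach_bruteforce(
    g: PangenomeGraph, cover: PathCover
) -> dict[str, list[str | None]]:
    """Backward scan of each cover path for the last vertex reaching ``v``."""
    reach = reach_table(g)
    table: dict[str, list[str | None]] = {v: [None] * len(cover) for v in g.vertices}
    for i, path in enumerate(cover.paths):
        for v in g.vertices:
            rv = reach[v]
            for w in reversed(path):
                if w in rv:
                    table[v][i] = w
                    break
    return table


def chain_quadratic_exact(anchors: AnchorSet, g: PangenomeGraph) -> list[float]:
    """Quadratic chaining DP under the *exact* distance gap model.

    Graph-side gaps use true shortest-path distances ``D`` and exact
    cycle lengths, so the optimum here is always at least the optimum of
    the path-cover model on the same instance (smaller gaps).
    """
    if len(anchors) > _MAX_ANCHORS:
        raise ValueError(f"oracle guard: more than {_MAX_ANCHORS} anchors")
    D = all_pairs_shortest(g)
    dcyc = cycle_dist_exact(g, D)
    reach: Callable[[str, str], bool] = lambda a, b: D[(a, b)] < inf
    on_cycle: Callable[[str], bool] = lambda v: dcyc[v] < inf

    def gap_g(a: Anchor, b: Anchor) -> float:
        base = b.x - a.y - 1
        if a.vertex != b.vertex:
            return base + D[(a.vertex, b.vertex)]
        if a.y < b.x:
            return base
        return base + dcyc[a.vertex]

    n = len(anchors)
    C: list[float] = [a.weight for a in anchors]
    order = sorted(range(n), key=lambda j: (anchors[j].c, j))
    for pos, j in enumerate(order):
        b = anchors[j]
        for i in order[:pos]:
            a = anchors[i]
            if precedes(a, b, reach, on_cycle):
                cand = C[i] + b.weight - gap_q(a, b) - gap_g(a, b)
                if cand > C[j]:
                    C[j] = cand
    return C


def naive_range_max(
    pairs: list[tuple[float, float]], l: float, r: float
) -> float:
    """Linear-scan maximum over values with ``l < key < r``; ``-inf`` if none."""
    best = -inf
    for key, value in pairs:
        if l < key < r and value > best:
            best = value
    return best
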