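"""One-time graph preprocessing for co-linear chaining.

The chaining algorithm needs, for each weakly connected component of the
graph:

* a small path cover ``P`` (every vertex on at least one path),
* a vertex ordering ``rank`` that is increasing along every cover path,
* ``last2reach(v, i)``: the last vertex on cover path ``P_i`` that can
  reach ``v`` by any walk,
* ``D(last2reach(v, i), v)``: the exact shortest-path distance from that
  vertex to ``v``,
* ``dist2begin(v, i)``: label length from the start of ``P_i`` to ``v``,
* ``Dcyc(v)``: the length of the shortest path-cover-restricted closed
  walk through ``v`` (finite exactly on vertices that lie on a proper
  cycle).

From these tables the path-cover-restricted distance ``dist_pc(v1, v2)``
is an upper bound on the true shortest-path distance that can be
evaluated in ``O(|paths(v1)|)`` time, which is what makes the sparse
chaining recurrence fast.

Computing a minimum path cover is NP-hard on graphs with cycles, so the
cover is built heuristically: back edges found by a depth-first search
inside each strongly connected component are removed, a *minimum* path
cover of the resulting DAG is computed by a minimum-flow reduction, and
a flow-based lower bound on the cyclic graph certifies how far from
optimal the heuristic can be.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import inf
from typing import Iterable, TextIO

import networkx as nx

from panchain.graph_io import PangenomeGraph, weak_components

__all__ = [
    "PathCover",
    "ComponentIndex",
    "GraphIndex",
    "dagify",
    "minimum_path_cover_dag",
    "path_cover_lower_bound",
    "compute_rank",
    "compute_last2reach",
    "compute_dist_from_last2reach",
    "compute_dist2begin",
    "compute_cycle_dist",
    "build_index",
    "save_index",
    "load_index",
]

INDEX_FORMAT_VERSION = 1


# ---------------------------------------------------------------------
# path cover
# ---------------------------------------------------------------------


@dataclass
class PathCover:
    """An ordered set of paths covering every vertex of a component.

    ``paths`` are vertex-id sequences following edges of the derived DAG.
    Path indices are 0-based in code; positions reported by
    :meth:`index_on` are 1-based.
    """

    paths: list[list[str]]
    paths_of: dict[str, list[int]] = field(init=False)
    _pos: dict[tuple[str, int], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.paths_of = {}
        self._pos = {}
        for i, path in enumerate(self.paths):
            seen: set[str] = set()
            for pos, v in enumerate(path, start=1):
                if v in seen:
                    raise ValueError(f"vertex {v!r} repeats within path {i}")
                seen.add(v)
                self.paths_of.setdefault(v, []).append(i)
                self._pos[(v, i)] = pos

    def __len__(self) -> int:
        return len(self.paths)

    def index_on(self, v: str, i: int) -> int:
        """1-based position of ``v`` on path ``i`` (KeyError if absent)."""
        return self._pos[(v, i)]

    def covers(self, vertices: Iterable[str]) -> bool:
        return all(v in self.paths_of for v in vertices)


# ---------------------------------------------------------------------
# DAG-ification by DFS back-edge removal within SCCs
# ---------------------------------------------------------------------


def dagify(g: PangenomeGraph) -> tuple[PangenomeGraph, set[tuple[str, str]]]:
    """Remove DFS back edges inside each strongly connected component.

    Within each SCC a depth-first search starts from the smallest vertex
    id and visits sorted adjacency; an edge pointing to a vertex on the
    current DFS stack is a back edge and is dropped.  Since every cycle
    lies inside one SCC and every cycle of the DFS forest contains a back
    edge, the result is acyclic.  Edges between SCCs are never removed,
    so the number of weak components is preserved.
    """
    removed: set[tuple[str, str]] = set()
    sccs = list(nx.strongly_connected_components(_to_nx(g)))
    for scc in sccs:
        if len(scc) == 1:
            v = next(iter(scc))
            if g.has_edge(v, v):
                removed.add((v, v))
            continue
        members = set(scc)
        start = min(members)
        on_stack: set[str] = set()
        visited: set[str] = set()
        # iterative DFS, restricted to intra-SCC edges
        stack: list[tuple[str, Iterable[str]]] = [(start, iter(g.out_neighbors(start)))]
        visited.add(start)
        on_stack.add(start)
        while stack:
            v, it = stack[-1]
            advanced = False
            for u in it:
                if u not in members:
                    continue
                if u in on_stack:
                    removed.add((v, u))
                elif u not in visited:
                    visited.add(u)
                    on_stack.add(u)
                    stack.append((u, iter(g.out_neighbors(u))))
                    advanced = True
                    break
                # visited but not on stack: forward/cross edge, harmless
            if not advanced:
                stack.pop()
                on_stack.discard(v)

    dag = PangenomeGraph()
    for v in g.vertices:
        dag.add_vertex(v, g.label(v))
    for v, u in g.edges():
        if (v, u) not in removed:
            dag.add_edge(v, u)
    return dag, removed


def _to_nx(g: PangenomeGraph) -> nx.DiGraph:
    ng = nx.DiGraph()
    ng.add_nodes_from(g.vertices)
    ng.add_edges_from(g.edges())
    return ng


# ---------------------------------------------------------------------
# minimum path cover / min-flow lower bound
# ---------------------------------------------------------------------


def _min_flow(g: PangenomeGraph) -> tuple[int, dict[tuple[str, str], int]]:
    """Minimum flow on the split-vertex network built over ``g``.

    Every vertex ``v`` becomes an arc ``v- -> v+`` with demand 1; a global
    source feeds every ``v-`` and every ``v+`` feeds a global sink; each
    graph edge ``(u, v)`` becomes ``u+ -> v-``.  All non-demand arcs have
    demand 0 and unbounded capacity.  A feasible flow routes one
    source->v->sink unit per vertex; it is then reduced by a maximum flow
    from sink to source in the residual network (backward residual
    capacity = flow minus demand).  Returns the minimum flow value and
    the per-arc flow on the split network.
    """
    n = g.n_vertices
    if n == 0:
        return 0, {}
    SRC, SNK = ("__src__", ""), ("__snk__", "")

    def vminus(v: str) -> tuple[str, str]:
        return (v, "-")

    def vplus(v: str) -> tuple[str, str]:
        return (v, "+")

    flow: dict[tuple, int] = {}
    arcs: list[tuple] = []
    demand: dict[tuple, int] = {}
    for v in g.vertices:
        for a in ((SRC, vminus(v)), (vminus(v), vplus(v)), (vplus(v), SNK)):
            arcs.append(a)
            flow[a] = 1
            demand[a] = 0
        demand[(vminus(v), vplus(v))] = 1
    for u, v in g.edges():
        a = (vplus(u), vminus(v))
        arcs.append(a)
        flow[a] = 0
        demand[a] = 0

    # residual network for flow reduction: forward capacity unbounded
    # (cap at n: a reduction never needs more), backward = flow - demand.
    # Backward arcs are routed through a private intermediate node so a
    # self-loop's split arcs cannot alias each other's residual capacity.
    res = nx.DiGraph()
    for (a, b) in arcs:
        res.add_edge(a, b, capacity=n)
        back = flow[(a, b)] - demand[(a, b)]
        if back > 0:
            mid = ("__back__", a, b)
            res.add_edge(b, mid, capacity=back)
            res.add_edge(mid, a, capacity=back)
    value, reduction = nx.maximum_flow(
        res, SNK, SRC, flow_func=nx.algorithms.flow.edmonds_karp
    )
    for (a, b) in arcs:
        mid = ("__back__", a, b)
        inc = reduction.get(a, {}).get(b, 0)
        dec = reduction.get(b, {}).get(mid, 0)
        f = flow[(a, b)] + inc - dec
        flow[(a, b)] = f
        assert f >= demand[(a, b)]
    return n - value, {a: flow[a] for a in arcs}


def path_cover_lower_bound(g: PangenomeGraph) -> int:
    """Minimum-flow lower bound on the size of any path cover of ``g``.

    Any path cover yields a feasible flow of the same value on the
    split-vertex network, so the minimum flow value is a lower bound on
    the minimum path cover size.  Cycles are allowed.
    """
    value, _ = _min_flow(g)
    return value


def minimum_path_cover_dag(g: PangenomeGraph) -> PathCover:
    """Minimum path cover of a DAG via the min-flow reduction.

    The minimum flow on the split-vertex network equals the minimum path
    cover size on a DAG; the final flow decomposes into source-to-sink
    paths whose ``v- -> v+`` arcs spell the cover paths.
    """
    if not nx.is_directed_acyclic_graph(_to_nx(g)):
        raise ValueError("minimum_path_cover_dag requires an acyclic graph")
    if g.n_vertices == 0:
        return PathCover(paths=[])
    value, flow = _min_flow(g)

    # greedy flow decomposition; adjacency sorted for determinism
    out_flow: dict[tuple, dict[tuple, int]] = {}
    for (a, b), f in flow.items():
        if f > 0:
            out_flow.setdefault(a, {})[b] = f
    SRC = ("__src__", "")
    SNK = ("__snk__", "")
    paths: list[list[str]] = []
    for _ in range(value):
        node = SRC
        path: list[str] = []
        while node != SNK:
            nxt = min(b for b, f in out_flow[node].items() if f > 0)
            out_flow[node][nxt] -= 1
            if node[1] == "-" and nxt[1] == "+" and node[0] == nxt[0]:
                path.append(node[0])
            node = nxt
        paths.append(path)
    cover = PathCover(paths=paths)
    assert cover.covers(g.vertices), "flow decomposition missed a vertex"
    return cover


# ---------------------------------------------------------------------
# rank
# ---------------------------------------------------------------------


def compute_rank(dag: PangenomeGraph) -> dict[str, int]:
    """Topological order of the DAG as ranks ``1..|V|``.

    Ties are broken by vertex id (Kahn's algorithm with a heap), so the
    result is deterministic.  Because cover paths follow DAG edges, any
    topological order is strictly increasing along every cover path.
    """
    import heapq

    indeg = {v: len(dag.in_neighbors(v)) for v in dag.vertices}
    ready = [v for v in dag.vertices if indeg[v] == 0]
    heapq.heapify(ready)
    rank: dict[str, int] = {}
    r = 0
    while ready:
        v = heapq.heappop(ready)
        r += 1
        rank[v] = r
        for u in dag.out_neighbors(v):
            indeg[u] -= 1
            if indeg[u] == 0:
                heapq.heappush(ready, u)
    if r != dag.n_vertices:
        raise ValueError("graph contains a cycle; rank requires a DAG")
    return rank


# ---------------------------------------------------------------------
# iterative last2reach / distance propagation
# ---------------------------------------------------------------------


def compute_last2reach(
    g: PangenomeGraph, cover: PathCover, rank: dict[str, int]
) -> tuple[dict[str, list[int]], int]:
    """Label propagation for ``last2reach(v, i)`` on the cyclic graph.

    ``l2r[v][i]`` holds the rank of the last vertex on cover path ``P_i``
    that reaches ``v`` (0 if none).  Initialized to ``rank(v)`` for ``v``
    on ``P_i``; full passes over vertices in increasing rank take maxima
    over in-neighbors until a pass changes nothing.  Every vertex of
    ``P_i`` that reaches an in-neighbor of ``v`` also reaches ``v``, and
    ranks increase along the path, so the running maximum converges to
    the rank of the true last reaching vertex in at most ``|V|``
    value-changing passes.  Returns the table and the count of
    value-changing passes (the final confirming pass is not counted).
    """
    k = len(cover)
    order = sorted(g.vertices, key=lambda v: rank[v])
    l2r: dict[str, list[int]] = {v: [0] * k for v in g.vertices}
    for i, path in enumerate(cover.paths):
        for v in path:
            l2r[v][i] = rank[v]
    gamma = 0
    for _ in range(g.n_vertices + 1):
        changed = False
        for v in order:
            row = l2r[v]
            for u in g.in_neighbors(v):
                urow = l2r[u]
                for i in range(k):
                    if urow[i] > row[i]:
                        row[i] = urow[i]
                        changed = True
        if not changed:
            break
        gamma += 1
    else:  # pragma: no cover - the |V|-pass convergence bound precludes this
        raise RuntimeError("last2reach propagation failed to converge in |V| passes")
    return l2r, gamma


def compute_dist_from_last2reach(
    g: PangenomeGraph,
    cover: PathCover,
    l2r: dict[str, list[int]],
    rank: dict[str, int],
) -> tuple[dict[str, list[float]], int]:
    """Iteratively compute ``D(last2reach(v, i), v)`` for all ``(v, i)``.

    Restricted Bellman-Ford relaxation: a shortest path from
    ``t = last2reach(v, i)`` to ``v`` can only visit vertices ``w`` with
    ``last2reach(w, i) = t`` (any later path vertex reaching ``w`` would
    also reach ``v``), so relaxation only crosses edges whose endpoints
    share the same l2r entry.  Base value 0 where ``v`` itself is its
    last2reach.  Entries are ``inf`` where ``last2reach`` is undefined or
    not yet reached; at convergence every defined entry is finite and
    exact.  Returns the table and the count of value-changing passes.
    """
    k = len(cover)
    order = sorted(g.vertices, key=lambda v: rank[v])
    d: dict[str, list[float]] = {v: [inf] * k for v in g.vertices}
    for v in g.vertices:
        for i in range(k):
            if l2r[v][i] == rank[v]:
                d[v][i] = 0
    gamma = 0
    for _ in range(g.n_vertices + 1):
        changed = False
        for v in order:
            row = d[v]
            lrow = l2r[v]
            for u in g.in_neighbors(v):
                edge_len = g.label_len(u)
                urow_d = d[u]
                urow_l = l2r[u]
                for i in range(k):
                    if lrow[i] and urow_l[i] == lrow[i]:
                        cand = urow_d[i] + edge_len
                        if cand < row[i]:
                            row[i] = cand
                            changed = True
        if not changed:
            break
        gamma += 1
    else:  # pragma: no cover
        raise RuntimeError("distance propagation failed to converge in |V| passes")
    return d, gamma


def compute_dist2begin(
    cover: PathCover, g: PangenomeGraph
) -> dict[str, dict[int, int]]:
    """Label-length prefix sums along every cover path.

    ``dist2begin[v][i]`` is the total label length of the vertices
    strictly before ``v`` on path ``P_i``; 0 for the first vertex.
    """
    table: dict[str, dict[int, int]] = {}
    for i, path in enumerate(cover.paths):
        acc = 0
        for v in path:
            table.setdefault(v, {})[i] = acc
            acc += g.label_len(v)
    return table


# ---------------------------------------------------------------------
# per-component index
# ---------------------------------------------------------------------


@dataclass
class ComponentIndex:
    """Preprocessing tables for one weakly connected component."""

    vertices: list[str]
    label_len: dict[str, int]
    n_edges: int
    cover: PathCover
    rank: dict[str, int]
    l2r: dict[str, list[int]]  # rank of last2reach(v,i), 0 = absent
    d_l2r: dict[str, list[float]]  # D(last2reach(v,i), v), inf = absent
    dist2begin: dict[str, dict[int, int]]
    cyc: dict[str, float]  # path-cover cycle distance, inf off-cycle
    gamma_l: int
    gamma_d: int
    lower_bound: int
    removed_edges: set[tuple[str, str]]
    rank_to_vertex: dict[int, str] = field(init=False)

    def __post_init__(self) -> None:
        self.rank_to_vertex = {r: v for v, r in self.rank.items()}

    @property
    def n_paths(self) -> int:
        return len(self.cover)

    def last2reach_vertex(self, v: str, i: int) -> str | None:
        r = self.l2r[v][i]
        return self.rank_to_vertex[r] if r else None

    def on_cycle(self, v: str) -> bool:
        return self.cyc[v] < inf

    def reaches(self, v1: str, v2: str) -> bool:
        """Whether ``v1`` reaches ``v2`` (path-cover tables are exact here)."""
        return self.dist_pc(v1, v2) < inf

    def dist_pc(self, v1: str, v2: str) -> float:
        """Path-cover-restricted distance from ``v1`` to ``v2``.

        For each cover path through ``v1`` the walk follows the path up
        to ``alpha`` -- ``v2`` itself if it lies on the path at or after
        ``v1``, otherwise ``last2reach(v2, i)`` provided that vertex is
        at or after ``v1`` -- and finishes with the shortest path from
        ``alpha`` to ``v2``.  The minimum over paths is an upper bound
        on the true shortest-path distance, finite exactly when ``v2``
        is reachable from ``v1``.  ``dist_pc(v, v) = 0`` by convention.
        """
        if v1 == v2:
            return 0
        best: float = inf
        for i in self.cover.paths_of[v1]:
            pos1 = self.cover.index_on(v1, i)
            d2b = self.dist2begin
            if i in d2b.get(v2, ()) and self.cover.index_on(v2, i) >= pos1:
                cand = d2b[v2][i] - d2b[v1][i]
            else:
                alpha = self.last2reach_vertex(v2, i)
                if alpha is None or self.cover.index_on(alpha, i) < pos1:
                    continue
                cand = d2b[alpha][i] - d2b[v1][i] + self.d_l2r[v2][i]
            if cand < best:
                best = cand
        return best


def compute_cycle_dist(idx: ComponentIndex, g: PangenomeGraph) -> dict[str, float]:
    """Path-cover-restricted shortest closed-walk length per vertex.

    ``Dcyc(v) = min over out-neighbors u of |sigma(v)| + dist_pc(u, v)``;
    finite exactly for vertices on a proper cycle (a self-loop
    contributes ``|sigma(v)|`` through ``dist_pc(v, v) = 0``).
    """
    cyc: dict[str, float] = {}
    for v in g.vertices:
        best: float = inf
        lv = g.label_len(v)
        for u in g.out_neighbors(v):
            cand = lv + idx.dist_pc(u, v)
            if cand < best:
                best = cand
        cyc[v] = best
    return cyc


# ---------------------------------------------------------------------
# whole-graph index
# ---------------------------------------------------------------------


@dataclass
class GraphIndex:
    """Preprocessing tables for every weak component of a graph."""

    components: list[ComponentIndex]
    component_of: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.component_of = {}
        for ci, comp in enumerate(self.components):
            for v in comp.vertices:
                self.component_of[v] = ci

    @property
    def n_components(self) -> int:
        return len(self.components)


def _build_component(g: PangenomeGraph) -> ComponentIndex:
    dag, removed = dagify(g)
    cover = minimum_path_cover_dag(dag)
    rank = compute_rank(dag)
    l2r, gamma_l = compute_last2reach(g, cover, rank)
    d_l2r, gamma_d = compute_dist_from_last2reach(g, cover, l2r, rank)
    d2b = compute_dist2begin(cover, g)
    lb = path_cover_lower_bound(g)
    idx = ComponentIndex(
        vertices=g.vertices,
        label_len={v: g.label_len(v) for v in g.vertices},
        n_edges=g.n_edges,
        cover=cover,
        rank=rank,
        l2r=l2r,
        d_l2r=d_l2r,
        dist2begin=d2b,
        cyc={},
        gamma_l=gamma_l,
        gamma_d=gamma_d,
        lower_bound=lb,
        removed_edges=removed,
    )
    idx.cyc = compute_cycle_dist(idx, g)
    return idx


def build_index(g: PangenomeGraph) -> GraphIndex:
    """Run the full preprocessing pipeline on every weak component."""
    comps = [_build_component(c) for c in weak_components(g)]
    return GraphIndex(components=comps)


# ---------------------------------------------------------------------
# serialization (versioned JSON; inf encoded as null)
# ---------------------------------------------------------------------


def _enc(x: float) -> float | None:
    return None if x == inf else x


def _dec(x: float | None) -> float:
    return inf if x is None else x


def save_index(index: GraphIndex, stream: TextIO) -> None:
    doc = {
        "format_version": INDEX_FORMAT_VERSION,
        "components": [
            {
                "vertices": c.vertices,
                "label_len": c.label_len,
                "n_edges": c.n_edges,
                "cover": c.cover.paths,
                "rank": c.rank,
                "l2r": c.l2r,
                "d_l2r": {v: [_enc(x) for x in row] for v, row in c.d_l2r.items()},
                "dist2begin": {
                    v: {str(i): d for i, d in row.items()}
                    for v, row in c.dist2begin.items()
                },
                "cyc": {v: _enc(x) for v, x in c.cyc.items()},
                "gamma_l": c.gamma_l,
                "gamma_d": c.gamma_d,
                "lower_bound": c.lower_bound,
                "removed_edges": sorted(list(e) for e in c.removed_edges),
            }
            for c in index.components
        ],
    }
    json.dump(doc, stream, indent=1)


def load_index(stream: TextIO) -> GraphIndex:
    doc = json.load(stream)
    version = doc.get("format_version")
    if version != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index format version: {version!r}")
    comps = []
    for c in doc["components"]:
        comps.append(
            ComponentIndex(
                vertices=list(c["vertices"]),
                label_len={v: int(n) for v, n in c["label_len"].items()},
                n_edges=int(c["n_edges"]),
                cover=PathCover(paths=[list(p) for p in c["cover"]]),
                rank={v: int(r) for v, r in c["rank"].items()},
                l2r={v: [int(x) for x in row] for v, row in c["l2r"].items()},
                d_l2r={v: [_dec(x) for x in row] for v, row in c["d_l2r"].items()},
                dist2begin={
                    v: {int(i): int(d) for i, d in row.items()}
                    for v, row in c["dist2begin"].items()
                },
                cyc={v: _dec(x) for v, x in c["cyc"].items()},
                gamma_l=int(c["gamma_l"]),
                gamma_d=int(c["gamma_d"]),
                lower_bound=int(c["lower_bound"]),
                removed_edges={tuple(e) for e in c["removed_edges"]},
            )
        )
    return GraphIndex(components=comps)
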