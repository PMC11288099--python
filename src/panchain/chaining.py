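"""Iterative co-linear chaining on cyclic pangenome graphs.

Anchors are exact matches ``(v, [x..y], [c..d])`` between a substring of
one vertex label and a substring of the query (1-based inclusive, equal
spans).  A chain is an ordered subset of anchors in which each anchor
precedes the next: query intervals strictly increase and the graph
positions are connected by a walk (possibly looping through cycles).
The chain score is the sum of anchor weights minus query-side and
graph-side gap penalties, where graph-side distances are the
path-cover-restricted distances from :mod:`panchain.preprocess`.

The sparse algorithm keeps one range-maximum search tree per cover
path, keyed by anchor query end-points ``M[j].d`` and holding a
*separable* encoding of chain scores, so that the best admissible
predecessor of an anchor is a single range-maximum query.  On a DAG one
sweep over the vertices in rank order solves the problem exactly; with
cycles the sweep is repeated until a fixpoint, which is reached after
at most ``N`` value-changing passes.  Correctness of the task schedule
is arbitrated by the quadratic reference DP
(:func:`chain_quadratic_pc`), not by the algebra alone.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from math import inf
from typing import Callable, Iterator, Sequence

from panchain.preprocess import ComponentIndex, GraphIndex

__all__ = [
    "Anchor",
    "AnchorSet",
    "RangeMaxTree",
    "Task",
    "ChainResult",
    "precedes",
    "gap_q",
    "gap_g_pc",
    "build_task_array",
    "sort_tasks",
    "chain",
    "traceback",
    "chain_quadratic_pc",
]

logger = logging.getLogger(__name__)

# task stages, in execution order at a vertex
STAGE_INTERLEAVED = 0
STAGE_AFTER_VERTEX = 1
STAGE_CYCLE = 2

# task kinds; at equal position a query runs before an update so that a
# same-vertex predecessor is visible only when its end lies strictly
# before the successor's start
KIND_QUERY = 0
KIND_UPDATE = 1


@dataclass(frozen=True)
class Anchor:
    """An exact match between ``sigma(vertex)[x..y]`` and ``Q[c..d]``."""

    vertex: str
    x: int
    y: int
    c: int
    d: int
    weight: float = -1.0  # sentinel: default to the match length

    def __post_init__(self) -> None:
        if not (1 <= self.x <= self.y):
            raise ValueError(f"bad graph interval [{self.x}..{self.y}]")
        if not (1 <= self.c <= self.d):
            raise ValueError(f"bad query interval [{self.c}..{self.d}]")
        if self.y - self.x != self.d - self.c:
            raise ValueError("graph and query intervals must have equal span")
        if self.weight == -1.0:
            object.__setattr__(self, "weight", self.y - self.x + 1)
        if self.weight < 0:
            raise ValueError("anchor weight must be non-negative")

    @property
    def span(self) -> int:
        return self.y - self.x + 1


class AnchorSet:
    """An ordered array ``M[1..N]`` of anchors (0-based in code)."""

    def __init__(self, anchors: Sequence[Anchor] = ()) -> None:
        self.anchors: list[Anchor] = list(anchors)

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self) -> Iterator[Anchor]:
        return iter(self.anchors)

    def __getitem__(self, j: int) -> Anchor:
        return self.anchors[j]

    def append(self, a: Anchor) -> None:
        self.anchors.append(a)


# ---------------------------------------------------------------------
# precedence and gap costs
# ---------------------------------------------------------------------


def precedes(
    a: Anchor,
    b: Anchor,
    reach: Callable[[str, str], bool],
    on_cycle: Callable[[str], bool],
) -> bool:
    """Whether anchor ``a`` precedes anchor ``b``.

    On different vertices: the query intervals must be disjoint in order
    (``a.d < b.c``) and ``a.vertex`` must reach ``b.vertex``.  On the
    same vertex the graph intervals must additionally be in order, or the
    vertex must lie on a proper cycle (the chain loops back around).
    """
    if a.d >= b.c:
        return False
    if a.vertex != b.vertex:
        return reach(a.vertex, b.vertex)
    return a.y < b.x or on_cycle(a.vertex)


def gap_q(a: Anchor, b: Anchor) -> int:
    """Characters of the query skipped between anchors ``a`` and ``b``."""
    return b.c - a.d - 1


def gap_g_pc(a: Anchor, b: Anchor, comp: ComponentIndex) -> float:
    """Graph-side gap under the path-cover-restricted distance.

    Three cases: different vertices use ``dist_pc`` between the vertices;
    same vertex with ordered graph intervals needs no walk; same vertex
    otherwise loops around the shortest path-cover-restricted cycle.
    Requires ``precedes(a, b)``; an infinite distance then indicates an
    internally inconsistent index and raises.
    """
    base = b.x - a.y - 1
    if a.vertex != b.vertex:
        dist = comp.dist_pc(a.vertex, b.vertex)
    elif a.y < b.x:
        dist = 0
    else:
        dist = comp.cyc[a.vertex]
    if dist == inf:
        raise RuntimeError(
            f"infinite graph distance between anchors on {a.vertex!r} and "
            f"{b.vertex!r} despite claimed precedence"
        )
    return base + dist


# ---------------------------------------------------------------------
# range-maximum search tree
# ---------------------------------------------------------------------


class RangeMaxTree:
    """Fixed-key segment tree supporting max-update and open-interval RMQ.

    Leaves are (key, value) pairs with distinct numeric keys;
    ``update(k, val)`` keeps the running maximum at the leaf and
    ``rmq(l, r)`` returns the maximum value (and its payload) over keys
    strictly inside ``(l, r)``.  Both run in ``O(log n)``.  Payloads
    disambiguate equal values deterministically (smallest payload wins).
    """

    __slots__ = ("keys", "_m", "_size", "_val", "_arg")

    def __init__(self, keys: Sequence[float]) -> None:
        self.keys = sorted(set(keys))
        m = max(1, len(self.keys))
        size = 1
        while size < m:
            size *= 2
        self._m = m
        self._size = size
        self._val: list[float] = [-inf] * (2 * size)
        self._arg: list[int | None] = [None] * (2 * size)

    def reset(self) -> None:
        self._val = [-inf] * (2 * self._size)
        self._arg = [None] * (2 * self._size)

    def _better(self, v1: float, a1, v2: float, a2) -> bool:
        if v1 != v2:
            return v1 > v2
        if a2 is None:
            return a1 is not None
        return a1 is not None and a1 < a2

    def update(self, key: float, value: float, payload: int | None = None) -> None:
        i = bisect_left(self.keys, key)
        if i >= len(self.keys) or self.keys[i] != key:
            raise KeyError(f"key {key!r} not among tree keys")
        node = self._size + i
        if not self._better(value, payload, self._val[node], self._arg[node]):
            return
        self._val[node] = value
        self._arg[node] = payload
        node //= 2
        while node:
            left, right = 2 * node, 2 * node + 1
            if self._better(
                self._val[left], self._arg[left], self._val[right], self._arg[right]
            ):
                self._val[node] = self._val[left]
                self._arg[node] = self._arg[left]
            else:
                self._val[node] = self._val[right]
                self._arg[node] = self._arg[right]
            node //= 2

    def rmq(self, l: float, r: float) -> tuple[float, int | None]:
        """Max (value, payload) over leaves with ``l < key < r``."""
        lo = bisect_left(self.keys, l)
        if lo < len(self.keys) and self.keys[lo] == l:
            lo += 1
        hi = bisect_left(self.keys, r)
        best_v: float = -inf
        best_a: int | None = None
        lo += self._size
        hi += self._size
        while lo < hi:
            if lo & 1:
                if self._better(self._val[lo], self._arg[lo], best_v, best_a):
                    best_v, best_a = self._val[lo], self._arg[lo]
                lo += 1
            if hi & 1:
                hi -= 1
                if self._better(self._val[hi], self._arg[hi], best_v, best_a):
                    best_v, best_a = self._val[hi], self._arg[hi]
            lo //= 2
            hi //= 2
        return best_v, best_a


# ---------------------------------------------------------------------
# task array
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class Task:
    """One scheduled tree operation of the chaining sweep.

    ``exec_rank`` is the rank of the vertex at which the task fires;
    ``stage`` orders interleaved < after-vertex < cycle within a vertex;
    ``pos`` is the within-vertex coordinate (anchor start for queries,
    anchor end for updates); ``path`` is the cover-path index the task
    touches (-1 for cycle-stage tasks, which use a per-vertex tree);
    ``shift`` precomputes ``dist2begin(alpha, path) + D(alpha, M[j].v)``
    for query tasks.
    """

    exec_rank: int
    stage: int
    pos: int
    kind: int
    anchor: int
    path: int
    shift: float = 0.0

    def sort_key(self) -> tuple:
        return (self.exec_rank, self.stage, self.pos, self.kind, self.anchor)


def sort_tasks(tasks: list[Task]) -> list[Task]:
    """Total, stable task order of the sweep."""
    return sorted(tasks, key=Task.sort_key)


def _component_tasks(
    anchors: AnchorSet, local: list[int], comp: ComponentIndex
) -> list[Task]:
    """Build the (unsorted) task array for the anchors of one component."""
    tasks: list[Task] = []
    for j in local:
        a = anchors[j]
        v = a.vertex
        if v not in comp.rank:
            raise KeyError(f"anchor {j} references unknown vertex {v!r}")
        if a.y > comp.label_len[v]:
            raise ValueError(
                f"anchor {j}: interval [{a.x}..{a.y}] exceeds |sigma({v!r})|"
            )
        rv = comp.rank[v]
        d2b = comp.dist2begin[v]
        for p in comp.cover.paths_of[v]:
            tasks.append(Task(rv, STAGE_INTERLEAVED, a.y, KIND_UPDATE, j, p))
            # interleaved query: predecessors already stored on path p at
            # or before v; alpha = v itself, no trailing shortest path
            tasks.append(
                Task(rv, STAGE_INTERLEAVED, a.x, KIND_QUERY, j, p, shift=d2b[p])
            )
        for p in range(comp.n_paths):
            u = comp.last2reach_vertex(v, p)
            if u is not None and u != v:
                # predecessors between v and u on path p become visible
                # only once u has been fully processed
                shift = comp.dist2begin[u][p] + comp.d_l2r[v][p]
                tasks.append(
                    Task(comp.rank[u], STAGE_AFTER_VERTEX, a.x, KIND_QUERY, j, p, shift)
                )
        if comp.cyc[v] < inf:
            tasks.append(Task(rv, STAGE_CYCLE, a.x, KIND_QUERY, j, -1))
    return tasks


def build_task_array(anchors: AnchorSet, index: GraphIndex) -> list[Task]:
    """Task array for a full anchor set (all components), unsorted.

    Per anchor and relevant cover path: an interleaved update at the
    anchor's end, an interleaved query at its start, an after-vertex
    query at ``last2reach`` when that differs from the anchor's vertex,
    and a cycle-stage query when the vertex lies on a proper cycle --
    at most ``4 N |P|`` tasks.
    """
    groups = _group_by_component(anchors, index)
    tasks: list[Task] = []
    for ci, local in groups.items():
        tasks.extend(_component_tasks(anchors, local, index.components[ci]))
    return tasks


def _group_by_component(
    anchors: AnchorSet, index: GraphIndex
) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for j, a in enumerate(anchors):
        if a.vertex not in index.component_of:
            raise KeyError(f"anchor {j} references unknown vertex {a.vertex!r}")
        groups.setdefault(index.component_of[a.vertex], []).append(j)
    return groups


# ---------------------------------------------------------------------
# the iterative algorithm
# ---------------------------------------------------------------------


@dataclass
class ChainResult:
    """Scores, parent pointers and the best chain of one chaining run.

    ``gamma_c`` is the count of value-changing passes (at least 1: the
    mandatory first pass is counted even when it changes nothing);
    ``n_passes`` additionally includes the final confirming pass.  Both
    are maxima over the weak components the anchors touch.
    """

    anchors: AnchorSet
    scores: list[float]
    parent: list[int | None]
    best_score: float
    best_index: int | None
    best_chain: list[int]
    gamma_c: int
    n_passes: int
    converged: bool
    #: per-component diagnostics: component id -> (gamma_c, n_passes,
    #: per-pass maxima of the component's scores)
    per_component: dict[int, tuple[int, int, list[float]]] = field(
        default_factory=dict
    )


def _run_cycle_stage(
    comp: ComponentIndex,
    vertex: str,
    members: list[int],
    anchors: AnchorSet,
    C: list[float],
    parent: list[int | None],
    trees: list[RangeMaxTree],
) -> bool:
    """Same-vertex chaining around the shortest cycle through ``vertex``.

    A per-vertex tree holds every anchor of the vertex (any interval
    overlap is admissible: the walk loops around the cycle).  Anchors are
    processed by start coordinate; an improvement is written back to the
    cycle tree and to the cover-path trees immediately, so gains can
    cascade within the stage.  Gains this ordering misses are picked up
    in the next pass.
    """
    dcyc = comp.cyc[vertex]
    tree = RangeMaxTree([anchors[j].d for j in members])
    for j in members:
        a = anchors[j]
        tree.update(a.d, C[j] + a.d + a.y, j)
    d2b = comp.dist2begin[vertex]
    changed = False
    for j in sorted(members, key=lambda j: (anchors[j].x, j)):
        a = anchors[j]
        val, arg = tree.rmq(-inf, a.c)
        if val == -inf:
            continue
        cand = val + a.weight + 2 - a.c - a.x - dcyc
        if cand > C[j]:
            C[j] = cand
            parent[j] = arg
            changed = True
            tree.update(a.d, C[j] + a.d + a.y, j)
            for p in comp.cover.paths_of[vertex]:
                trees[p].update(a.d, C[j] + a.d + a.y + d2b[p], j)
    return changed


def _chain_component(
    anchors: AnchorSet,
    local: list[int],
    comp: ComponentIndex,
    C: list[float],
    parent: list[int | None],
    max_iters: int,
) -> tuple[int, int, list[float], bool]:
    tasks = sort_tasks(_component_tasks(anchors, local, comp))
    keys = [anchors[j].d for j in local]
    trees = [RangeMaxTree(keys) for _ in range(comp.n_paths)]
    cycle_members: dict[str, list[int]] = {}
    for j in local:
        v = anchors[j].vertex
        if comp.cyc[v] < inf:
            cycle_members.setdefault(v, []).append(j)

    history: list[float] = []
    gamma = 0
    passes = 0
    converged = False
    while passes < max_iters + 1:
        passes += 1
        for t in trees:
            t.reset()
        cycle_done: set[str] = set()
        changed = False
        for task in tasks:
            a = anchors[task.anchor]
            if task.stage == STAGE_CYCLE:
                v = a.vertex
                if v in cycle_done:
                    continue
                cycle_done.add(v)
                if _run_cycle_stage(
                    comp, v, cycle_members[v], anchors, C, parent, trees
                ):
                    changed = True
            elif task.kind == KIND_UPDATE:
                value = C[task.anchor] + a.d + a.y + comp.dist2begin[a.vertex][task.path]
                trees[task.path].update(a.d, value, task.anchor)
            else:
                val, arg = trees[task.path].rmq(-inf, a.c)
                if val == -inf:
                    continue
                cand = val + a.weight + 2 - a.c - a.x - task.shift
                if cand > C[task.anchor]:
                    C[task.anchor] = cand
                    parent[task.anchor] = arg
                    changed = True
        history.append(max(C[j] for j in local))
        if not changed:
            converged = True
            break
        gamma += 1
        if gamma > len(local):  # pragma: no cover - N-pass bound holds
            raise RuntimeError("chaining exceeded the N-pass convergence bound")
    if not converged:
        logger.warning(
            "chaining did not converge within %d passes on a component with "
            "%d anchors",
            max_iters,
            len(local),
        )
    return max(1, gamma), passes, history, converged


def chain(
    anchors: AnchorSet, index: GraphIndex, max_iters: int | None = None
) -> ChainResult:
    """Optimal co-linear chain of ``anchors`` under the path-cover gaps.

    Scores ``C[j]`` start at ``weight(M[j])`` and never decrease; passes
    over the sorted task array repeat until a pass changes no score.
    Anchors on different weak components never chain together.  The best
    chain is recovered by parent-pointer traceback and re-scored as a
    consistency check.
    """
    n = len(anchors)
    if n == 0:
        return ChainResult(anchors, [], [], -inf, None, [], 0, 0, True)
    C: list[float] = [a.weight for a in anchors]
    parent: list[int | None] = [None] * n
    groups = _group_by_component(anchors, index)
    gamma_c = 0
    n_passes = 0
    converged = True
    per_component: dict[int, tuple[int, int, list[float]]] = {}
    for ci in sorted(groups):
        local = groups[ci]
        cap = max_iters if max_iters is not None else len(local)
        g, p, hist, ok = _chain_component(
            anchors, local, index.components[ci], C, parent, cap
        )
        per_component[ci] = (g, p, hist)
        gamma_c = max(gamma_c, g)
        n_passes = max(n_passes, p)
        converged = converged and ok
    best_index = max(range(n), key=lambda j: (C[j], -j))
    result = ChainResult(
        anchors=anchors,
        scores=C,
        parent=parent,
        best_score=C[best_index],
        best_index=best_index,
        best_chain=[],
        gamma_c=gamma_c,
        n_passes=n_passes,
        converged=converged,
        per_component=per_component,
    )
    if converged:
        result.best_chain = traceback(result, best_index, index)
    return result


def traceback(
    result: ChainResult, j_star: int, index: GraphIndex
) -> list[int]:
    """Anchor indices of the best chain ending at ``j_star``.

    Follows parent pointers and verifies that consecutive anchors
    satisfy precedence and that the re-computed score equals
    ``C[j_star]``.  Only valid once the scores have converged.
    """
    if not result.converged:
        raise RuntimeError("traceback requires converged chaining scores")
    anchors = result.anchors
    chain_idx: list[int] = []
    j: int | None = j_star
    seen: set[int] = set()
    while j is not None:
        if j in seen:  # pragma: no cover - defensive
            raise RuntimeError("cycle in parent pointers")
        seen.add(j)
        chain_idx.append(j)
        j = result.parent[j]
    chain_idx.reverse()

    score = anchors[chain_idx[0]].weight
    for i, jj in zip(chain_idx, chain_idx[1:]):
        a, b = anchors[i], anchors[jj]
        comp = index.components[index.component_of[a.vertex]]
        if not precedes(a, b, comp.reaches, comp.on_cycle):
            raise RuntimeError(f"traceback produced non-preceding pair ({i}, {jj})")
        score += b.weight - gap_q(a, b) - gap_g_pc(a, b, comp)
    if abs(score - result.scores[j_star]) > 1e-9 * max(1.0, abs(score)):
        raise RuntimeError(
            f"re-computed chain score {score} != C[{j_star}] = "
            f"{result.scores[j_star]}"
        )
    return chain_idx


# ---------------------------------------------------------------------
# quadratic reference DP (path-cover gap model)
# ---------------------------------------------------------------------


def chain_quadratic_pc(anchors: AnchorSet, index: GraphIndex) -> list[float]:
    """Exact ``O(N^2)`` DP for the path-cover gap model.

    Sorts anchors by query start and relaxes every preceding pair.  Used
    as the reference oracle for :func:`chain`; cap the instance size.
    """
    n = len(anchors)
    if n > 500:
        raise ValueError("quadratic reference capped at 500 anchors")
    C: list[float] = [a.weight for a in anchors]
    groups = _group_by_component(anchors, index)
    for ci, local in groups.items():
        comp = index.components[ci]
        order = sorted(local, key=lambda j: (anchors[j].c, j))
        for pos, j in enumerate(order):
            b = anchors[j]
            for i in order[:pos]:
                a = anchors[i]
                if precedes(a, b, comp.reaches, comp.on_cycle):
                    cand = C[i] + b.weight - gap_q(a, b) - gap_g_pc(a, b, comp)
                    if cand > C[j]:
                        C[j] = cand
    return C
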