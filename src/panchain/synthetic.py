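"""Seeded generators of graphs, anchors and adversarial instances.

Everything a test needs can be generated here deterministically: random
cyclic graphs (a DAG backbone plus rank-decreasing back edges, emulating
the cycles that inversion and duplication variants introduce), planted
anchor chains along a random walk (emulating the output of a seeding
stage, with decoy anchors as noise), the two-vertex-cycle worst case for
the convergence bound, and a minimal exact k-mer seeder that confines
anchors to single vertices.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from panchain.chaining import Anchor, AnchorSet
from panchain.graph_io import PangenomeGraph, Query

__all__ = [
    "InstanceSpec",
    "random_cyclic_graph",
    "plant_chain_anchors",
    "worst_case_instance",
    "kmer_seed",
]

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class InstanceSpec:
    """Parameters of one synthetic instance; the seed fixes every choice.

    ``edge_density`` is the probability of each extra forward edge beyond
    the backbone chain that keeps the graph weakly connected.
    ``n_back_edges`` rank-decreasing edges are added to create cycles.
    Label lengths are drawn uniformly from ``label_len_range`` (bp).
    """

    n_vertices: int = 20
    edge_density: float = 0.1
    n_back_edges: int = 3
    label_len_range: tuple[int, int] = (1, 8)
    n_true: int = 8
    n_noise: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise ValueError("n_vertices must be >= 1")
        if min(self.n_back_edges, self.n_true, self.n_noise) < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.label_len_range
        if not (1 <= lo <= hi):
            raise ValueError("label_len_range must satisfy 1 <= lo <= hi")


def _vid(i: int, n: int) -> str:
    width = len(str(n))
    return f"v{i + 1:0{width}d}"


def random_cyclic_graph(spec: InstanceSpec) -> PangenomeGraph:
    """Random weakly connected graph with planted back edges.

    Vertices are laid out in a topological order ``v1 < v2 < ...``; a
    backbone chain ``v_i -> v_{i+1}`` keeps the graph in one weak
    component, extra forward edges are sampled independently with
    probability ``edge_density``, and ``n_back_edges`` strictly
    rank-decreasing edges close cycles.  With ``n_back_edges = 0`` the
    result is acyclic.
    """
    rng = random.Random(f"{spec.seed}-graph")
    n = spec.n_vertices
    lo, hi = spec.label_len_range
    g = PangenomeGraph()
    ids = [_vid(i, n) for i in range(n)]
    for vid in ids:
        label = "".join(rng.choice(_ALPHABET) for _ in range(rng.randint(lo, hi)))
        g.add_vertex(vid, label)
    for i in range(n - 1):
        g.add_edge(ids[i], ids[i + 1])
    for i in range(n):
        for j in range(i + 2, n):
            if rng.random() < spec.edge_density:
                g.add_edge(ids[i], ids[j])
    if n >= 2:
        for _ in range(spec.n_back_edges):
            j = rng.randrange(1, n)
            i = rng.randrange(0, j)
            g.add_edge(ids[j], ids[i])
    return g


def _sample_walk(
    g: PangenomeGraph, rng: random.Random, min_steps: int
) -> list[str]:
    """A random walk of at least ``min_steps`` vertices, if one exists."""
    best: list[str] = []
    starts = [min(g.vertices)] + [rng.choice(g.vertices) for _ in range(7)]
    for v in starts:
        walk = [v]
        while len(walk) < max(min_steps, 2 * min_steps):
            nbrs = g.out_neighbors(walk[-1])
            if not nbrs:
                break
            walk.append(rng.choice(nbrs))
        if len(walk) >= min_steps:
            return walk
        if len(walk) > len(best):
            best = walk
    # deterministic fallback: from the smallest vertex, always take the
    # smallest out-neighbor (follows the backbone / loops through cycles)
    walk = [min(g.vertices)]
    while len(walk) < min_steps:
        nbrs = g.out_neighbors(walk[-1])
        if not nbrs:
            break
        walk.append(nbrs[0])
    return walk if len(walk) >= min_steps else best


def plant_chain_anchors(
    g: PangenomeGraph, spec: InstanceSpec
) -> tuple[Query, AnchorSet, list[int]]:
    """Plant a valid chain along a random walk and add decoy anchors.

    The walk may revisit vertices through cycles; its spelled string is
    the query.  ``n_true`` full-label anchors are cut at a contiguous
    block of walk steps (a run of perfect seed matches along the true
    alignment path), so consecutive planted anchors satisfy precedence
    with zero query gaps (same-vertex repeats imply a proper cycle) and
    the planted chain carries a strong positive score.  ``n_noise``
    decoys are placed at random positions and need not match the query
    text.  Returns the query, the anchors (planted first, then decoys)
    and the indices of the planted chain.
    """
    rng = random.Random(f"{spec.seed}-anchors")
    walk = _sample_walk(g, rng, spec.n_true)
    if len(walk) < max(1, spec.n_true):
        raise ValueError(
            f"graph admits no walk with {spec.n_true} steps for planting"
        )
    offsets = [0]
    for v in walk:
        offsets.append(offsets[-1] + g.label_len(v))
    sequence = "".join(g.label(v) for v in walk)
    query = Query(name=f"sim{spec.seed}", sequence=sequence)

    anchors = AnchorSet()
    start = rng.randrange(0, len(walk) - spec.n_true + 1)
    for t in range(start, start + spec.n_true):
        v = walk[t]
        lv = g.label_len(v)
        anchors.append(
            Anchor(vertex=v, x=1, y=lv, c=offsets[t] + 1, d=offsets[t] + lv)
        )
    planted = list(range(spec.n_true))

    qlen = len(sequence)
    for _ in range(spec.n_noise):
        v = rng.choice(g.vertices)
        span = min(g.label_len(v), qlen)
        width = rng.randint(1, span)
        x = rng.randint(1, g.label_len(v) - width + 1)
        c = rng.randint(1, qlen - width + 1)
        anchors.append(
            Anchor(vertex=v, x=x, y=x + width - 1, c=c, d=c + width - 1)
        )
    return query, anchors, planted


def worst_case_instance(n_anchors: int) -> tuple[PangenomeGraph, AnchorSet]:
    """The two-vertex-cycle instance that forces slow convergence.

    Two single-character vertices form a cycle; anchors alternate
    between them (odd indices on ``v1``, even on ``v2``) with adjacent
    unit query intervals, so each anchor precedes the next and the
    optimal chain uses all of them.  Weights are set to 100x the largest
    pairwise gap so that gap costs never dominate.  With a single-path
    cover the maximum chaining score grows by only one anchor weight per
    pass after the first, so the sweep needs on the order of
    ``n_anchors`` passes in total.
    """
    if n_anchors < 2 or n_anchors % 2:
        raise ValueError("n_anchors must be even and >= 2")
    g = PangenomeGraph()
    g.add_vertex("v1", "A")
    g.add_vertex("v2", "C")
    g.add_edge("v1", "v2")
    g.add_edge("v2", "v1")

    # gap bounds on this graph: query gap <= n-2 (adjacent unit
    # intervals), graph gap <= 1 (cycle length 2 between/around the
    # unit-label vertices)
    max_gap = max(1, (n_anchors - 2) + 1)
    weight = 100 * max_gap
    anchors = AnchorSet()
    for j in range(1, n_anchors + 1):
        v = "v1" if j % 2 else "v2"
        anchors.append(Anchor(vertex=v, x=1, y=1, c=j, d=j, weight=weight))
    return g, anchors


def kmer_seed(g: PangenomeGraph, q: Query, k: int) -> AnchorSet:
    """All exact length-``k`` matches between ``q`` and single vertex labels.

    Every match becomes an anchor of weight ``k``; coordinates are
    1-based inclusive and the output is ordered by (vertex id, label
    offset, query offset).  This is a minimal stand-in for a minimizer
    seeding stage; anchors never span more than one vertex.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hits: dict[str, list[int]] = {}
    seq = q.sequence
    for c in range(len(seq) - k + 1):
        hits.setdefault(seq[c : c + k], []).append(c + 1)
    anchors = AnchorSet()
    for v in g.vertices:
        label = g.label(v)
        for x in range(len(label) - k + 1):
            for c in hits.get(label[x : x + k], ()):
                anchors.append(
                    Anchor(vertex=v, x=x + 1, y=x + k, c=c, d=c + k - 1, weight=k)
                )
    return anchors
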