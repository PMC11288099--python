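"""Shared fixtures: the toy cyclic graph, its hand-checked anchors, and
a seeded stream of random chaining instances used by several suites."""

from __future__ import annotations

import random

import pytest

from panchain.chaining import Anchor, AnchorSet
from panchain.graph_io import PangenomeGraph
from panchain.preprocess import GraphIndex, build_index
from panchain.synthetic import InstanceSpec, plant_chain_anchors, random_cyclic_graph


def make_toy_graph() -> PangenomeGraph:
    """Three vertices with a two-vertex cycle: v1 -> v2 <-> v3.

    Labels ACGT / GG / TTT, so the cycle through v2 has length 5 and the
    single cover path v1,v2,v3 carries prefix distances 0, 4, 6.
    """
    g = PangenomeGraph()
    g.add_vertex("v1", "ACGT")
    g.add_vertex("v2", "GG")
    g.add_vertex("v3", "TTT")
    g.add_edge("v1", "v2")
    g.add_edge("v2", "v3")
    g.add_edge("v3", "v2")
    return g


@pytest.fixture(scope="session")
def toy_graph() -> PangenomeGraph:
    return make_toy_graph()


@pytest.fixture(scope="session")
def toy_index(toy_graph: PangenomeGraph) -> GraphIndex:
    return build_index(toy_graph)


@pytest.fixture(scope="session")
def toy_anchors() -> AnchorSet:
    """Four anchors whose optimal chain revisits v2 through the cycle.

    Hand-scored: weights 3+2+3+2, query gaps 1+1+1 and zero graph gaps,
    so the best chain (a1, a2, a3, a4) scores 7.
    """
    return AnchorSet(
        [
            Anchor("v1", 2, 4, 1, 3),
            Anchor("v2", 1, 2, 5, 6),
            Anchor("v3", 1, 3, 8, 10),
            Anchor("v2", 1, 2, 12, 13),
        ]
    )


def random_instance(seed: int, max_vertices: int = 30):
    """One seeded random chaining instance: (graph, query, anchors, planted).

    Graphs stay small (<= 30 vertices, <= 60 edges, 0-6 back edges) and
    anchor sets stay below 40 so the quadratic references remain cheap.
    """
    rng = random.Random(seed)
    n = rng.randint(2, max_vertices)
    density = rng.uniform(0.0, 0.08)
    spec = InstanceSpec(
        n_vertices=n,
        edge_density=density,
        n_back_edges=rng.randint(0, 6),
        label_len_range=(1, 8),
        n_true=rng.randint(1, min(12, n)),
        n_noise=rng.randint(0, 28),
        seed=seed,
    )
    g = random_cyclic_graph(spec)
    if g.n_edges > 60:
        spec = InstanceSpec(
            n_vertices=n,
            edge_density=0.02,
            n_back_edges=rng.randint(0, 6),
            label_len_range=(1, 8),
            n_true=spec.n_true,
            n_noise=spec.n_noise,
            seed=seed,
        )
        g = random_cyclic_graph(spec)
    query, anchors, planted = plant_chain_anchors(g, spec)
    return g, query, anchors, planted


def random_dag_instance(seed: int, max_vertices: int = 30):
    """Like :func:`random_instance` but with no back edges (acyclic)."""
    rng = random.Random(seed)
    n = rng.randint(2, max_vertices)
    spec = InstanceSpec(
        n_vertices=n,
        edge_density=rng.uniform(0.0, 0.08),
        n_back_edges=0,
        label_len_range=(1, 8),
        n_true=rng.randint(1, min(12, n)),
        n_noise=rng.randint(0, 28),
        seed=seed,
    )
    g = random_cyclic_graph(spec)
    query, anchors, planted = plant_chain_anchors(g, spec)
    return g, query, anchors, planted
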