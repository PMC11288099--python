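"""The iterative chaining algorithm, its task schedule and range trees."""

from math import inf

import pytest
from hypothesis import given, settings, strategies as st

from panchain.chaining import (
    Anchor,
    AnchorSet,
    RangeMaxTree,
    build_task_array,
    chain,
    chain_quadratic_pc,
    gap_g_pc,
    gap_q,
    precedes,
    sort_tasks,
    traceback,
    KIND_QUERY,
    KIND_UPDATE,
    STAGE_AFTER_VERTEX,
    STAGE_CYCLE,
    STAGE_INTERLEAVED,
    Task,
)
from panchain.graph_io import PangenomeGraph
from panchain.oracle import naive_range_max, reach_table, cycle_dist_exact, all_pairs_shortest
from panchain.preprocess import build_index
from panchain.synthetic import worst_case_instance

from conftest import random_instance


class TestAnchor:
    def test_default_weight_is_span(self):
        a = Anchor("v", 2, 4, 5, 7)
        assert a.weight == 3

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(x=3, y=2, c=1, d=1),  # reversed graph interval
            dict(x=1, y=2, c=3, d=3),  # span mismatch
            dict(x=1, y=1, c=0, d=0),  # query coordinates are 1-based
        ],
    )
    def test_invalid_anchor_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Anchor("v", **kwargs)


class TestPrecedence:
    def _preds(self, g):
        reach = reach_table(g)
        dc = cycle_dist_exact(g, all_pairs_shortest(g))
        return (lambda a, b: a in reach[b]), (lambda v: dc[v] < inf)

    def test_same_vertex_on_cycle_overlapping_graph_intervals(self, toy_graph):
        reach, on_cycle = self._preds(toy_graph)
        a = Anchor("v2", 1, 2, 5, 6)
        b = Anchor("v2", 1, 2, 12, 13)
        assert precedes(a, b, reach, on_cycle)

    def test_same_vertex_acyclic_needs_ordered_graph_intervals(self):
        g = PangenomeGraph()
        g.add_vertex("a", "ACGT")
        reach, on_cycle = self._preds(g)
        first = Anchor("a", 1, 2, 1, 2)
        second = Anchor("a", 2, 3, 5, 6)  # overlaps first on the label
        third = Anchor("a", 3, 4, 5, 6)
        assert not precedes(first, second, reach, on_cycle)
        assert precedes(first, third, reach, on_cycle)

    def test_query_order_is_mandatory(self, toy_graph):
        reach, on_cycle = self._preds(toy_graph)
        a = Anchor("v1", 1, 2, 5, 6)
        b = Anchor("v2", 1, 2, 6, 7)  # c <= a.d
        assert not precedes(a, b, reach, on_cycle)

    @pytest.mark.parametrize("seed", range(15))
    def test_strict_partial_order_on_random_sets(self, seed):
        g, _, anchors, _ = random_instance(seed, max_vertices=15)
        reach, on_cycle = self._preds(g)
        n = len(anchors)
        for i in range(n):
            assert not precedes(anchors[i], anchors[i], reach, on_cycle)
            for j in range(n):
                if precedes(anchors[i], anchors[j], reach, on_cycle):
                    assert not precedes(anchors[j], anchors[i], reach, on_cycle)


class TestGaps:
    def test_gap_q_arithmetic(self):
        assert gap_q(Anchor("v", 1, 3, 1, 3), Anchor("v", 5, 5, 5, 5)) == 1
        assert gap_q(Anchor("v", 1, 4, 1, 4), Anchor("v", 5, 5, 5, 5)) == 0

    def test_toy_fixture_zero_graph_gaps(self, toy_index, toy_anchors):
        comp = toy_index.components[0]
        a1, a2, a3, a4 = toy_anchors
        assert gap_q(a1, a2) == 1
        assert gap_g_pc(a1, a2, comp) == 0
        assert gap_g_pc(a3, a4, comp) == 0

    def test_same_vertex_ordered_intervals_no_distance_term(self, toy_index):
        comp = toy_index.components[0]
        a = Anchor("v3", 1, 2, 1, 2)
        b = Anchor("v3", 3, 3, 9, 9)  # y=2 < x=3: stays on the vertex
        assert gap_g_pc(a, b, comp) == 0  # 3 - 2 - 1, no distance term


class TestTaskArray:
    def test_acyclic_anchor_two_tasks(self):
        g = PangenomeGraph()
        g.add_vertex("a", "ACGT")
        index = build_index(g)
        tasks = build_task_array(AnchorSet([Anchor("a", 1, 2, 1, 2)]), index)
        kinds = sorted(t.kind for t in tasks)
        assert len(tasks) == 2 and kinds == [KIND_QUERY, KIND_UPDATE]

    def test_cycle_vertex_anchor_four_tasks(self, toy_index):
        tasks = build_task_array(AnchorSet([Anchor("v2", 1, 2, 1, 2)]), toy_index)
        assert len(tasks) == 4
        stages = sorted(t.stage for t in tasks)
        assert stages == [
            STAGE_INTERLEAVED,
            STAGE_INTERLEAVED,
            STAGE_AFTER_VERTEX,
            STAGE_CYCLE,
        ]

    def test_single_path_dag_exactly_2n_tasks(self):
        g = PangenomeGraph()
        for v in ("a", "b", "c"):
            g.add_vertex(v, "ACGT")
        g.add_edge("a", "b")
        g.add_edge("b", "c")
        index = build_index(g)
        anchors = AnchorSet(
            [Anchor(v, 1, 2, 3 * i + 1, 3 * i + 2) for i, v in enumerate("abcab")]
        )
        tasks = build_task_array(anchors, index)
        assert len(tasks) == 2 * len(anchors)

    def test_bound_4np(self, toy_index, toy_anchors):
        tasks = build_task_array(toy_anchors, toy_index)
        n_paths = toy_index.components[0].n_paths
        assert len(tasks) <= 4 * len(toy_anchors) * n_paths

    def test_unknown_vertex_rejected(self, toy_index):
        with pytest.raises(KeyError, match="unknown vertex"):
            build_task_array(AnchorSet([Anchor("zz", 1, 1, 1, 1)]), toy_index)

    def test_sort_order(self):
        q3 = Task(1, STAGE_INTERLEAVED, 3, KIND_QUERY, 0, 0)
        u3 = Task(1, STAGE_INTERLEAVED, 3, KIND_UPDATE, 1, 0)
        u2 = Task(1, STAGE_INTERLEAVED, 2, KIND_UPDATE, 2, 0)
        q4 = Task(1, STAGE_INTERLEAVED, 4, KIND_QUERY, 3, 0)
        av = Task(1, STAGE_AFTER_VERTEX, 1, KIND_QUERY, 4, 0)
        assert sort_tasks([av, q4, u3, q3, u2]) == [u2, q3, u3, q4, av]


class TestRangeMaxTree:
    def test_open_interval_semantics(self):
        t = RangeMaxTree([1, 3, 5])
        t.update(1, 5, 0)
        t.update(3, 7, 1)
        assert t.rmq(0, 3) == (5, 0)
        assert t.rmq(0, 5) == (7, 1)
        assert t.rmq(3, 5) == (-inf, None)
        assert t.rmq(1, 3) == (-inf, None)

    def test_update_keeps_running_max(self):
        t = RangeMaxTree([2])
        t.update(2, 5, 0)
        t.update(2, 3, 1)
        assert t.rmq(0, 10) == (5, 0)

    def test_unknown_key_rejected(self):
        t = RangeMaxTree([1])
        with pytest.raises(KeyError):
            t.update(9, 1, 0)

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_matches_naive_scan(self, data):
        keys = data.draw(
            st.lists(st.integers(0, 50), min_size=1, max_size=20, unique=True)
        )
        tree = RangeMaxTree(keys)
        pairs: dict[float, float] = {}
        for _ in range(data.draw(st.integers(0, 40))):
            if data.draw(st.booleans()):
                k = data.draw(st.sampled_from(keys))
                v = data.draw(st.integers(-100, 100))
                tree.update(k, v)
                pairs[k] = max(pairs.get(k, -inf), v)
            else:
                l = data.draw(st.integers(-1, 51))
                r = data.draw(st.integers(-1, 51))
                got, _ = tree.rmq(l, r)
                assert got == naive_range_max(list(pairs.items()), l, r)


class TestChain:
    def test_toy_fixture_best_chain_revisits_v2(self, toy_index, toy_anchors):
        result = chain(toy_anchors, toy_index)
        assert result.best_score == 7
        assert result.best_chain == [0, 1, 2, 3]
        visited = [toy_anchors[j].vertex for j in result.best_chain]
        assert visited.count("v2") == 2
        assert result.scores == chain_quadratic_pc(toy_anchors, toy_index)

    def test_single_anchor(self, toy_index):
        result = chain(AnchorSet([Anchor("v1", 1, 3, 1, 3)]), toy_index)
        assert result.best_score == 3
        assert result.gamma_c == 1
        assert result.best_chain == [0]

    def test_empty_anchor_set(self, toy_index):
        result = chain(AnchorSet(), toy_index)
        assert result.best_chain == [] and result.scores == []

    def test_scores_never_below_weight(self, toy_index, toy_anchors):
        result = chain(toy_anchors, toy_index)
        assert all(
            s >= a.weight for s, a in zip(result.scores, toy_anchors)
        )

    def test_two_chainable_anchors_closed_form(self, toy_index):
        # max(w1, w2, w1 + w2 - gaps)
        a = Anchor("v1", 2, 4, 1, 3, weight=5)
        b = Anchor("v2", 1, 2, 5, 6, weight=1)
        result = chain(AnchorSet([a, b]), toy_index)
        assert result.scores == [5, 5 + 1 - 1 - 0]

    def test_anchors_in_different_components_never_chain(self):
        g = PangenomeGraph()
        g.add_vertex("a", "ACGT")
        g.add_vertex("b", "ACGT")
        index = build_index(g)
        anchors = AnchorSet([Anchor("a", 1, 2, 1, 2), Anchor("b", 1, 2, 5, 6)])
        result = chain(anchors, index)
        assert result.scores == [2, 2]

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_quadratic_reference_on_random_instances(self, seed):
        g, _, anchors, _ = random_instance(seed)
        index = build_index(g)
        result = chain(anchors, index)
        assert result.converged
        assert result.scores == chain_quadratic_pc(anchors, index)
        assert result.gamma_c <= max(1, len(anchors))

    @pytest.mark.parametrize("seed", range(10))
    def test_traceback_rescores_every_endpoint(self, seed):
        g, _, anchors, _ = random_instance(seed, max_vertices=12)
        index = build_index(g)
        result = chain(anchors, index)
        for j in range(len(anchors)):
            idxs = traceback(result, j, index)
            assert idxs[-1] == j  # re-scoring happens inside traceback

    def test_traceback_requires_convergence(self, toy_index, toy_anchors):
        result = chain(toy_anchors, toy_index)
        result.converged = False
        with pytest.raises(RuntimeError, match="converged"):
            traceback(result, 0, toy_index)


class TestWorstCase:
    def test_n8_pass_count_and_trajectory(self):
        """Two-vertex cycle, 8 anchors: the score front moves one anchor
        per pass, so the sweep needs N/2 + 1 passes in total."""
        g, anchors = worst_case_instance(8)
        index = build_index(g)
        assert index.components[0].cover.paths == [["v1", "v2"]]
        result = chain(anchors, index)
        assert result.scores == chain_quadratic_pc(anchors, index)
        assert len(result.best_chain) == 8
        assert result.n_passes == 8 // 2 + 1
        w = anchors[0].weight
        hist = result.per_component[0][2]
        # max score after pass 1 is N/2 + 1 anchor weights (minus the
        # small gap terms), then exactly one more weight per pass
        assert 4.9 <= hist[0] / w <= 5.0
        for prev, cur in zip(hist, hist[1:-1]):
            assert 0.99 <= (cur - prev) / w <= 1.01

    def test_n2_uses_both_anchors(self):
        g, anchors = worst_case_instance(2)
        index = build_index(g)
        result = chain(anchors, index)
        assert len(result.best_chain) == 2

    def test_monotone_scores_across_passes(self):
        g, anchors = worst_case_instance(8)
        index = build_index(g)
        result = chain(anchors, index)
        hist = result.per_component[0][2]
        assert hist == sorted(hist)
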