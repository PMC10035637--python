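"""Weighting, top-k selection, alignment-graph voting and the trace DP."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ehmmalign as ea
from ehmmalign.consensus import TraceError, validate_trace
from ehmmalign.merge_output import ExtendedAlignmentMap
from conftest import random_graph


class TestComputeWeights:
    @pytest.mark.parametrize("b,s,expected", [
        ((0, 0), (5, 5), (0.5, 0.5)),
        ((1, 0), (1, 1), (2 / 3, 1 / 3)),
        ((0, 0), (3, 1), (0.75, 0.25)),
    ])
    def test_size_times_odds_formula(self, b, s, expected):
        w = ea.compute_weights(b, s)
        assert w.weights == pytest.approx(expected, rel=1e-12)

    def test_log_space_stability_across_extreme_bitscores(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            b = rng.uniform(-500, 500, size=int(rng.integers(2, 40)))
            s = rng.integers(1, 50, size=b.size)
            w = ea.compute_weights(b, s)
            assert np.isfinite(w.weights).all()
            assert w.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_accepts_hmm_score_objects(self):
        scores = [ea.HmmScore(0, 1.0), ea.HmmScore(1, 0.0)]
        w = ea.compute_weights(scores, [1, 1])
        assert w.weights == pytest.approx((2 / 3, 1 / 3))


class TestSelectTopK:
    def test_top_two_renormalized(self):
        w = ea.HmmWeightVector(np.array([0.4, 0.3, 0.2, 0.1]), [0, 1, 2, 3])
        sel = ea.select_top_k(w, 2)
        assert sel.selected == [0, 1]
        assert sel.weights[[0, 1]] == pytest.approx((4 / 7, 3 / 7))
        assert sel.weights[[2, 3]] == pytest.approx((0.0, 0.0))

    def test_k_at_least_ensemble_size_is_identity(self):
        w = ea.HmmWeightVector(np.array([0.6, 0.4]), [0, 1])
        sel = ea.select_top_k(w, 10)
        assert sel.selected == [0, 1]
        assert sel.weights == pytest.approx((0.6, 0.4))

    def test_ties_broken_toward_smaller_index(self):
        w = ea.HmmWeightVector(np.array([0.25, 0.25, 0.25, 0.25]),
                               [0, 1, 2, 3])
        assert ea.select_top_k(w, 2).selected == [0, 1]

    def test_default_k_is_ten(self):
        assert ea.PipelineConfig().k == 10


def _map(qid, n, matched):
    m = np.array(matched, dtype=np.int64)
    slot = np.full(m.size, -1, dtype=np.int64)
    last = -1
    for i, c in enumerate(m):
        if c < 0:
            slot[i] = last + 1
        else:
            last = c
    return ExtendedAlignmentMap(qid, n, m, slot)


class TestBuildAlignmentGraph:
    def test_single_hmm_full_weight(self):
        emap = _map("q", 4, [0, 1, 2, 3])
        w = ea.HmmWeightVector(np.array([1.0]), [0])
        graph = ea.build_alignment_graph([emap], w, 4, 4)
        assert graph.edges == {(i, i): pytest.approx(1.0) for i in range(4)}

    def test_agreement_sums_weights(self):
        maps = [_map("q", 8, [-1, -1, 5]), _map("q", 8, [-1, -1, 5])]
        w = ea.HmmWeightVector(np.array([0.6, 0.4]), [0, 1])
        graph = ea.build_alignment_graph(maps, w, 3, 8)
        assert graph.edges[(2, 5)] == pytest.approx(1.0)

    def test_disagreement_keeps_separate_edges(self):
        maps = [_map("q", 8, [-1, -1, 5]), _map("q", 8, [-1, -1, 6])]
        w = ea.HmmWeightVector(np.array([0.6, 0.4]), [0, 1])
        graph = ea.build_alignment_graph(maps, w, 3, 8)
        assert graph.edges[(2, 5)] == pytest.approx(0.6)
        assert graph.edges[(2, 6)] == pytest.approx(0.4)

    def test_out_of_range_map_rejected(self):
        emap = _map("q", 9, [8])
        w = ea.HmmWeightVector(np.array([1.0]), [0])
        with pytest.raises(TraceError):
            ea.build_alignment_graph([emap], w, 1, 8)


class TestMaxWeightTrace:
    def test_empty_graph_empty_trace(self):
        trace = ea.max_weight_trace(ea.WeightedAlignmentGraph(3, 3, {}))
        assert trace.pairs == [] and trace.total_weight == 0.0

    def test_crossing_heavy_edges(self):
        # (0,1)=0.9 and (1,0)=0.8 cross; (0,0)=0.5 conflicts with both picks
        graph = ea.WeightedAlignmentGraph(
            2, 2, {(0, 1): 0.9, (1, 0): 0.8, (0, 0): 0.5})
        trace = ea.max_weight_trace(graph)
        assert trace.total_weight == pytest.approx(0.9)
        assert trace.pairs == [(0, 1)]

    def test_chain_takes_every_compatible_edge(self):
        graph = ea.WeightedAlignmentGraph(
            3, 4, {(0, 0): 0.2, (1, 2): 0.2, (2, 3): 0.2})
        trace = ea.max_weight_trace(graph)
        assert trace.pairs == [(0, 0), (1, 2), (2, 3)]
        assert trace.total_weight == pytest.approx(graph.total_weight)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            graph = random_graph(rng, int(rng.integers(1, 9)),
                                 int(rng.integers(1, 9)), 10)
            dp = ea.max_weight_trace(graph)
            oracle = ea.brute_force_trace(graph)
            assert dp.total_weight == pytest.approx(oracle.total_weight,
                                                    abs=1e-9)
            validate_trace(dp, graph)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_adding_an_edge_never_decreases_the_optimum(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_graph(rng, 6, 6, 8)
        base = ea.max_weight_trace(graph).total_weight
        edges = dict(graph.edges)
        key = (int(rng.integers(0, 6)), int(rng.integers(0, 6)))
        edges[key] = max(edges.get(key, 0.0), float(rng.uniform(0.05, 1.0)))
        grown = ea.max_weight_trace(ea.WeightedAlignmentGraph(6, 6, edges))
        assert grown.total_weight >= base - 1e-12

    def test_weight_bounded_by_total_edge_weight(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            graph = random_graph(rng, 5, 5, 8)
            trace = ea.max_weight_trace(graph)
            assert trace.total_weight <= graph.total_weight + 1e-12


class TestBruteForceTrace:
    def test_single_edge(self):
        graph = ea.WeightedAlignmentGraph(2, 2, {(1, 0): 0.3})
        assert ea.brute_force_trace(graph).pairs == [(1, 0)]

    def test_two_crossing_edges_keeps_heavier(self):
        graph = ea.WeightedAlignmentGraph(2, 2, {(0, 1): 1.0, (1, 0): 2.0})
        trace = ea.brute_force_trace(graph)
        assert trace.pairs == [(1, 0)] and trace.total_weight == 2.0

    def test_compatible_chain_fully_selected(self):
        graph = ea.WeightedAlignmentGraph(3, 3, {(0, 0): 1.0, (1, 1): 1.0,
                                                 (2, 2): 1.0})
        assert ea.brute_force_trace(graph).total_weight == 3.0

    def test_instance_size_guard(self):
        edges = {(i, i): 1.0 for i in range(25)}
        with pytest.raises(TraceError):
            ea.brute_force_trace(ea.WeightedAlignmentGraph(25, 25, edges))
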