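import itertools

import numpy as np
import pytest

from i2g.core_model import LineGraph, synapse_from_mask
from i2g.graph_metrics import (
    Correspondence,
    augment_line_graphs,
    frobenius_error,
    graph_f1,
    match_synapses,
    permutation_pvalue,
    score_graphs,
)


def lg_from_edges(index, edges):
    n = len(index)
    pos = {s: i for i, s in enumerate(index)}
    m = np.zeros((n, n), dtype=np.uint8)
    for a, b in edges:
        m[pos[a], pos[b]] = m[pos[b], pos[a]] = 1
    return LineGraph(index, m)


class TestMatchSynapses:
    def _syn(self, sid, voxels):
        return synapse_from_mask(sid, voxels, 1.0)

    def test_identical_sets_fully_matched(self):
        syns = [self._syn(1, {(0, 0, 0)}), self._syn(2, {(0, 3, 3)})]
        corr = match_synapses(syns, syns)
        assert [(t, e) for t, e, _ in corr.pairs] == [(1, 1), (2, 2)]
        assert corr.unmatched_true == [] and corr.unmatched_est == []

    def test_greedy_resolves_competition_by_overlap(self):
        t1 = self._syn(1, {(0, 0, x) for x in range(50)})
        t2 = self._syn(2, {(0, 1, x) for x in range(40)})
        e1 = self._syn(1, {(0, 0, x) for x in range(50)} | {(0, 1, x) for x in range(20)})
        e2 = self._syn(2, {(0, 1, x) for x in range(20, 40)})
        corr = match_synapses([t1, t2], [e1, e2])
        assert {(t, e) for t, e, _ in corr.pairs} == {(1, 1), (2, 2)}

    def test_disjoint_sets_all_unmatched(self):
        corr = match_synapses(
            [self._syn(1, {(0, 0, 0)})], [self._syn(5, {(0, 9, 9)})]
        )
        assert corr.pairs == []
        assert corr.unmatched_true == [1]
        assert corr.unmatched_est == [5]

    def test_one_to_one_enforced(self):
        with pytest.raises(ValueError, match="one-to-one"):
            Correspondence(pairs=[(1, 1, 5), (1, 2, 3)], unmatched_true=[], unmatched_est=[])


class TestAugmentLineGraphs:
    def test_perfect_correspondence_preserves_edges(self):
        true_lg = lg_from_edges([1, 2, 3], [(1, 2), (2, 3)])
        est_lg = lg_from_edges([10, 20, 30], [(10, 20)])
        corr = Correspondence(
            pairs=[(1, 10, 5), (2, 20, 5), (3, 30, 5)], unmatched_true=[], unmatched_est=[]
        )
        ta, ea = augment_line_graphs(true_lg, est_lg, corr)
        assert ta.index == ea.index
        assert ta.edge_pairs() == {(("m", 1), ("m", 2)), (("m", 2), ("m", 3))}
        assert ea.edge_pairs() == {(("m", 1), ("m", 2))}

    def test_unmatched_nodes_get_zero_rows(self):
        true_lg = lg_from_edges([1, 2, 3], [(1, 2), (1, 3)])
        est_lg = lg_from_edges([10, 20, 99], [(10, 20), (10, 99)])
        corr = Correspondence(
            pairs=[(1, 10, 5), (2, 20, 4)], unmatched_true=[3], unmatched_est=[99]
        )
        ta, ea = augment_line_graphs(true_lg, est_lg, corr)
        assert len(ta) == len(ea) == 4
        i_t3 = ta.index.index(("t", 3))
        i_e99 = ta.index.index(("e", 99))
        assert ea.matrix[i_t3].sum() == 0  # absent from est graph
        assert ta.matrix[i_e99].sum() == 0  # absent from true graph
        assert ta.matrix[i_t3].sum() == 1  # kept its true edge
        assert ea.matrix[i_e99].sum() == 1

    def test_empty_graphs(self):
        corr = Correspondence(pairs=[], unmatched_true=[], unmatched_est=[])
        ta, ea = augment_line_graphs(LineGraph.empty(), LineGraph.empty(), corr)
        assert len(ta) == len(ea) == 0

    def test_unknown_ids_rejected(self):
        corr = Correspondence(pairs=[(9, 1, 2)], unmatched_true=[], unmatched_est=[])
        with pytest.raises(ValueError, match="unknown"):
            augment_line_graphs(
                lg_from_edges([1], []), lg_from_edges([1], []), corr
            )

    def test_augmentation_never_changes_tp(self):
        """Extra unmatched nodes add zero rows only: TP is invariant while
        FP/FN may grow."""
        true_lg = lg_from_edges([1, 2, 3], [(1, 2), (2, 3)])
        est_lg = lg_from_edges([1, 2, 3], [(1, 2)])
        ident = Correspondence(
            pairs=[(1, 1, 1), (2, 2, 1), (3, 3, 1)], unmatched_true=[], unmatched_est=[]
        )
        base = graph_f1(*augment_line_graphs(true_lg, est_lg, ident))
        true_big = lg_from_edges([1, 2, 3, 4], [(1, 2), (2, 3), (3, 4)])
        corr = Correspondence(
            pairs=[(1, 1, 1), (2, 2, 1), (3, 3, 1)], unmatched_true=[4], unmatched_est=[]
        )
        aug = graph_f1(*augment_line_graphs(true_big, est_lg, corr))
        assert aug.tp == base.tp
        assert aug.fn >= base.fn


class TestFrobeniusError:
    def test_identical_graphs_have_zero_error(self):
        lg = lg_from_edges([1, 2, 3], [(1, 2)])
        assert frobenius_error(lg, lg) == 0.0

    def test_two_differing_symmetric_pairs(self):
        a = lg_from_edges([1, 2, 3], [(1, 2)])
        b = lg_from_edges([1, 2, 3], [(1, 3)])
        assert frobenius_error(a, b) == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            def rand_lg():
                m = np.zeros((6, 6), dtype=np.uint8)
                iu = np.triu_indices(6, 1)
                e = (rng.random(15) < 0.4).astype(np.uint8)
                m[iu] = e
                return LineGraph(list(range(6)), m + m.T)

            a, b = rand_lg(), rand_lg()
            expected = 0.0
            for i in range(6):
                for j in range(6):
                    expected += (float(a.matrix[i, j]) - float(b.matrix[i, j])) ** 2
            assert abs(frobenius_error(a, b) - np.sqrt(expected)) <= 1e-12

    def test_symmetric_in_arguments(self):
        a = lg_from_edges([1, 2, 3], [(1, 2)])
        b = lg_from_edges([1, 2, 3], [(2, 3), (1, 3)])
        assert frobenius_error(a, b) == frobenius_error(b, a)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="size"):
            frobenius_error(lg_from_edges([1], []), lg_from_edges([1, 2], []))


class TestGraphF1:
    def test_identical_graphs(self):
        lg = lg_from_edges([1, 2, 3], [(1, 2), (2, 3)])
        gs = graph_f1(lg, lg)
        assert (gs.tp, gs.fp, gs.fn) == (2, 0, 0)
        assert (gs.precision, gs.recall, gs.f1) == (1.0, 1.0, 1.0)

    def test_worked_example(self):
        """Truth edges {(1,2),(2,3)} vs test {(1,2),(1,3)}: one common edge,
        one spurious, one missed."""
        truth = lg_from_edges([1, 2, 3], [(1, 2), (2, 3)])
        test = lg_from_edges([1, 2, 3], [(1, 2), (1, 3)])
        gs = graph_f1(truth, test)
        assert (gs.tp, gs.fp, gs.fn) == (1, 1, 1)
        assert gs.precision == 0.5
        assert gs.recall == 0.5
        assert gs.f1 == 0.5

    def test_empty_test_graph(self):
        truth = lg_from_edges([1, 2], [(1, 2)])
        gs = graph_f1(truth, lg_from_edges([1, 2], []))
        assert gs.recall == 0.0 and gs.f1 == 0.0

    def test_precision_recall_swap_under_argument_swap(self):
        a = lg_from_edges([1, 2, 3, 4], [(1, 2), (3, 4)])
        b = lg_from_edges([1, 2, 3, 4], [(1, 2), (2, 3), (1, 4)])
        ab, ba = graph_f1(a, b), graph_f1(b, a)
        assert ab.precision == ba.recall
        assert ab.recall == ba.precision
        assert ab.f1 == ba.f1

    def test_isolated_nodes_do_not_change_f1(self):
        """True negatives never enter the metric: padding both graphs with
        isolated synapses leaves precision/recall/F1 unchanged."""
        a = lg_from_edges([1, 2, 3], [(1, 2)])
        b = lg_from_edges([1, 2, 3], [(1, 2), (2, 3)])
        base = graph_f1(a, b)
        idx = [1, 2, 3, 7, 8, 9]
        a_pad = lg_from_edges(idx, [(1, 2)])
        b_pad = lg_from_edges(idx, [(1, 2), (2, 3)])
        padded = graph_f1(a_pad, b_pad)
        assert (padded.precision, padded.recall, padded.f1) == (
            base.precision,
            base.recall,
            base.f1,
        )
        assert frobenius_error(a_pad, b_pad) == frobenius_error(a, b)


class TestPermutationPvalue:
    def test_perfect_estimate_attains_minimum_pvalue(self):
        rng = np.random.default_rng(7)
        m = np.zeros((12, 12), dtype=np.uint8)
        iu = np.triu_indices(12, 1)
        e = (rng.random(len(iu[0])) < 0.3).astype(np.uint8)
        m[iu] = e
        lg = LineGraph(list(range(12)), m + m.T)
        p, summary = permutation_pvalue(lg, lg, B=999, seed=0)
        assert p == pytest.approx(1 / 1000)
        assert summary.observed == 0.0

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """n=3 truth with one edge: the null CDF can be enumerated over all
        8 symmetric graphs weighted by Bernoulli(p) edges."""
        truth = lg_from_edges([1, 2, 3], [(1, 2)])
        est = truth  # observed error 0; p = est density = 1/3
        B = 20000
        p_mc, summary = permutation_pvalue(truth, est, B=B, seed=3, smoothed=False)
        p_edge = est.density()
        exact = 0.0
        for bits in itertools.product([0, 1], repeat=3):
            w = np.prod([p_edge if b else 1 - p_edge for b in bits])
            g = lg_from_edges(
                [1, 2, 3],
                [e for e, b in zip([(1, 2), (1, 3), (2, 3)], bits) if b],
            )
            err = 1.0 - graph_f1(truth, g).f1
            if err <= summary.observed + 1e-12:
                exact += w
        se = np.sqrt(exact * (1 - exact) / B)
        assert abs(p_mc - exact) <= 3 * se

    def test_pvalue_in_half_open_unit_interval(self):
        truth = lg_from_edges([1, 2, 3, 4], [(1, 2), (3, 4)])
        for seed in range(5):
            p, _ = permutation_pvalue(truth, truth, B=50, seed=seed)
            assert 0.0 < p <= 1.0

    def test_invalid_b_rejected(self):
        lg = lg_from_edges([1, 2], [])
        with pytest.raises(ValueError, match="B"):
            permutation_pvalue(lg, lg, B=0)

    def test_frobenius_statistic_supported(self):
        truth = lg_from_edges([1, 2, 3, 4], [(1, 2), (2, 3)])
        est = lg_from_edges([1, 2, 3, 4], [(1, 2)])
        p, summary = permutation_pvalue(truth, est, B=200, statistic="frobenius", seed=1)
        assert summary.observed == pytest.approx(frobenius_error(truth, est))
        assert 0.0 < p <= 1.0


class TestScoreGraphs:
    def test_full_report_for_identical_pipelines(self):
        # 10 nodes keep the chance of a random tie with the truth negligible,
        # so the perfect estimate attains the smoothed minimum p of 1/(B+1)
        idx = list(range(10))
        edges = [(i, i + 1) for i in range(9)] + [(0, 5), (2, 7)]
        lg = lg_from_edges(idx, edges)
        corr = Correspondence(
            pairs=[(i, i, 1) for i in idx], unmatched_true=[], unmatched_est=[]
        )
        report = score_graphs(lg, lg, corr, B=499, seed=0)
        assert report.f1 == 1.0
        assert report.frobenius == 0.0
        assert report.p_value == pytest.approx(1 / 500)
        assert report.B == 499
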