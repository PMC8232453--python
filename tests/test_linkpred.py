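"""Link-prediction indices, hold-out splitting, and PR-AUC."""

import math

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from netclosure import (
    DirectedGraph,
    EvalProtocol,
    ScoredPair,
    candidate_pairs,
    evaluate,
    pr_auc,
    score_pair,
    split_old_new,
)


@pytest.fixture
def dag5():
    return DirectedGraph([(1, 2), (2, 3), (1, 3), (4, 2)])


class TestScores:
    def test_baseline_indices(self, dag5):
        # common set of (1, 3) is {2} with |N(2)| = 3
        assert score_pair(dag5, 1, 3, "DiCN") == 1.0
        assert score_pair(dag5, 1, 3, "DiAA") == pytest.approx(1 / math.log(3))
        assert score_pair(dag5, 1, 3, "DiRA") == pytest.approx(1 / 3)

    def test_closure_closeness_indices(self):
        g = DirectedGraph([(1, 2), (2, 3), (1, 3), (3, 4), (2, 4)])
        assert score_pair(g, 1, 4, "CCI") == pytest.approx(2.0)
        assert score_pair(g, 1, 4, "ECCI") == pytest.approx(2.0)

    def test_disjoint_neighborhoods_score_zero(self):
        g = DirectedGraph([(1, 2), (3, 4)])
        for m in ("DiCN", "DiAA", "DiRA", "CCI", "ECCI"):
            assert score_pair(g, 1, 4, m) == 0.0

    def test_self_pair_rejected(self, dag5):
        with pytest.raises(ValueError):
            score_pair(dag5, 1, 1, "DiCN")

    def test_unknown_method_rejected(self, dag5):
        with pytest.raises(ValueError, match="unknown method"):
            score_pair(dag5, 1, 3, "katz")

    @pytest.mark.parametrize("seed", range(3))
    def test_cci_factorizes_over_dicn(self, seed):
        from netclosure import random_directed_gnp, source_target_closure

        g = random_directed_gnp(15, 0.2, seed=seed)
        for s, t in list(candidate_pairs(g))[:50]:
            e_s = source_target_closure(g, s)[0] or 0.0
            e_t = source_target_closure(g, t)[1] or 0.0
            assert score_pair(g, s, t, "CCI") == pytest.approx(
                score_pair(g, s, t, "DiCN") * (e_s + e_t))


class TestCandidates:
    def test_counts(self):
        g = DirectedGraph([(1, 2)], nodes=[1, 2, 3])
        assert len(list(candidate_pairs(g))) == 5  # 9 - 3 self - 1 edge
        full = DirectedGraph([(a, b) for a in (1, 2) for b in (1, 2) if a != b])
        assert list(candidate_pairs(full)) == []
        empty = DirectedGraph(nodes=range(4))
        assert len(list(candidate_pairs(empty))) == 12


class TestPrAuc:
    def test_hand_rankings(self):
        def pairs(labels):
            return [ScoredPair(0, k, float(len(labels) - k), bool(l))
                    for k, l in enumerate(labels)]

        assert pr_auc(pairs([1, 1, 0])) == 1.0
        assert pr_auc(pairs([0, 1])) == 0.5
        assert pr_auc(pairs([1, 0, 1])) == pytest.approx((1 + 2 / 3) / 2)

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            pr_auc([ScoredPair(0, 1, 1.0, False)])

    def test_matches_sklearn_on_tie_free_scores(self):
        rng = np.random.default_rng(3)
        scores = rng.permutation(200) / 200.0
        labels = rng.random(200) < 0.3
        labels[0] = True
        mine = pr_auc([ScoredPair(0, k, s, bool(l))
                       for k, (s, l) in enumerate(zip(scores, labels))])
        assert mine == pytest.approx(average_precision_score(labels, scores))

    def test_random_scorer_near_prevalence(self):
        rng = np.random.default_rng(11)
        n, prev = 4000, 0.5
        labels = rng.random(n) < prev
        scores = rng.random(n)
        ap = pr_auc([ScoredPair(0, k, s, bool(l))
                     for k, (s, l) in enumerate(zip(scores, labels))])
        assert ap == pytest.approx(prev, abs=0.05)


class TestSplit:
    def test_temporal_takes_earliest_half(self):
        edges = [(i, i + 1) for i in range(10)]
        times = {e: float(100 - k) for k, e in enumerate(edges)}  # reversed
        g = DirectedGraph(edges, timestamps=times)
        g_old, e_new = split_old_new(g, EvalProtocol(temporal=True))
        assert g_old.n_edges == 5
        assert set(g_old.edges) == set(edges[5:])  # latest-inserted are earliest

    def test_temporal_requires_timestamps(self, dag5):
        with pytest.raises(ValueError, match="timestamps"):
            split_old_new(dag5, EvalProtocol(temporal=True))

    def test_future_edges_outside_old_nodes_excluded(self):
        edges = [(1, 2), (2, 3), (8, 9)]
        times = {(1, 2): 0.0, (2, 3): 1.0, (8, 9): 2.0}
        g = DirectedGraph(edges, timestamps=times)
        g_old, e_new = split_old_new(g, EvalProtocol(temporal=True))
        assert set(g_old.edges) == {(1, 2)}
        assert e_new == set()  # both future edges touch nodes outside V*

    def test_random_split_reproducible(self):
        from netclosure import random_directed_gnp

        g = random_directed_gnp(20, 0.3, seed=5)
        a = split_old_new(g, EvalProtocol(seed=7))
        b = split_old_new(g, EvalProtocol(seed=7))
        assert set(a[0].edges) == set(b[0].edges) and a[1] == b[1]


class TestEvaluate:
    def test_seeded_runs_identical(self):
        from netclosure import random_directed_gnp

        g = random_directed_gnp(30, 0.2, seed=21)
        proto = EvalProtocol(repeats=3, seed=17)
        df1 = evaluate(g, proto, ["DiCN", "CCI"])
        df2 = evaluate(g, proto, ["DiCN", "CCI"])
        assert df1.equals(df2)
        assert set(df1.columns) == {"DiCN", "CCI"}
        assert "mean" in df1.index

    def test_temporal_toy_graph_deterministic(self):
        edges = [(1, 2), (2, 3), (3, 4), (4, 1), (1, 3), (2, 4)]
        times = {e: float(k) for k, e in enumerate(edges)}
        g = DirectedGraph(edges, timestamps=times)
        df = evaluate(g, EvalProtocol(temporal=True), ["DiCN"])
        assert len(df) == 2  # single run + mean row
        assert 0.0 <= df.loc["mean", "DiCN"] <= 1.0
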