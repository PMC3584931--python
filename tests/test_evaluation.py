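"""Recall-precision measures, F1/Fmax and method ranking."""

import itertools

import numpy as np
import pytest

from hominf.evaluation import (
    RPCurve,
    RPPoint,
    f1,
    fmax,
    leaf_threshold_curve,
    rank_methods,
    threshold_curve,
    top20_curve,
)
from hominf.ontology import leaf_terms, load_ontology, propagate_max
from hominf.synthesize import single_target_example

from conftest import random_dag_edges


@pytest.fixture
def toy():
    return single_target_example()


class TestTop20:
    def test_figure_example_tier_one(self, toy):
        graph, truths, preds = toy
        pt = top20_curve(preds, truths, graph).points[0]
        assert pt.recall == pytest.approx(1 / 11)
        assert pt.precision == pytest.approx(0.5)

    def test_perfect_prediction(self, forked):
        truth = {"t": {"a", "b", "c"}}
        preds = {"t": {"a": 1.0, "b": 1.0, "c": 1.0}}
        pt = top20_curve(preds, truth, forked).points[0]
        assert (pt.recall, pt.precision) == (1.0, 1.0)

    def test_unpredicted_target_contributes_zero_recall(self, forked):
        truth = {"t1": {"a"}, "t2": {"d"}}
        preds = {"t1": {"a": 1.0}}
        pt = top20_curve(preds, truth, forked).points[0]
        assert pt.recall == pytest.approx(0.5)
        assert pt.precision == 1.0  # averaged over predicted targets only
        assert pt.n_predicted_targets == 1

    def test_tiers_are_distinct_score_classes(self, forked):
        truth = {"t": {"a", "b"}}
        preds = {"t": {"a": 0.8, "b": 0.8, "d": 0.3}}
        curve = top20_curve(preds, truth, forked)
        assert curve.points[0].precision == 1.0  # both 0.8 terms in tier 1
        assert curve.points[1].precision == pytest.approx(2 / 3)


class TestThreshold:
    def test_inclusive_boundary(self, forked):
        truth = {"t": {"a"}}
        preds = {"t": {"a": 0.82}}
        curve = threshold_curve(preds, truth, forked)
        pt = next(p for p in curve if abs(p.control - 0.82) < 1e-9)
        assert pt.recall == 1.0

    def test_zero_threshold_includes_everything(self, forked):
        truth = {"t": {"a"}}
        preds = {"t": {"a": 0.0, "d": 0.0}}
        pt = threshold_curve(preds, truth, forked).points[-1]
        assert pt.control == 0.0
        assert pt.recall == 1.0 and pt.precision == 0.5

    def test_has_101_points_and_monotone_recall(self, forked):
        rng = np.random.default_rng(5)
        truth = {"t": {"a", "b", "c"}}
        preds = {"t": {t: float(rng.random()) for t in ("a", "b", "d", "e")}}
        curve = threshold_curve(preds, truth, forked)
        assert len(curve) == 101
        recalls = [p.recall for p in curve]  # control decreasing 1.00 -> 0.00
        assert all(r2 >= r1 - 1e-12 for r1, r2 in zip(recalls, recalls[1:]))


class TestLeafThreshold:
    def test_figure_example(self, toy):
        graph, truths, preds = toy
        curve = leaf_threshold_curve(preds, truths, graph)
        pt = next(p for p in curve if abs(p.control - 0.80) < 1e-9)
        assert pt.recall == 0.0 and pt.precision == 0.0

    def test_exact_leaf_match_perfect_everywhere(self, forked):
        truth = {"t": {"a", "b", "c"}}
        preds = {"t": {"a": 1.0, "b": 1.0, "c": 1.0}}
        curve = leaf_threshold_curve(preds, truth, forked)
        assert all(p.recall == 1.0 and p.precision == 1.0 for p in curve)

    def test_over_general_prediction_scores_zero(self, forked):
        # predicting the whole ontology hides the true leaves as internal
        # nodes of the prediction, unless they are ontology leaves
        truth = {"t": {"a", "b"}}  # truth leaf: b (internal in ontology)
        preds = {"t": {t: 1.0 for t in forked.terms if t != "r"}}
        curve = leaf_threshold_curve(preds, truth, forked)
        assert curve.points[0].recall == 0.0


class TestF1Fmax:
    @pytest.mark.parametrize(
        "p,r,expected",
        [(0.5, 0.5, 0.5), (0.2, 1.0, 1 / 3), (0.0, 0.7, 0.0), (0.3, 0.0, 0.0)],
    )
    def test_f1(self, p, r, expected):
        assert f1(p, r) == pytest.approx(expected)

    def test_fmax_over_points(self):
        curve = RPCurve(
            measure="threshold",
            points=[
                RPPoint(1.0, 1.0, 0.2, 1),
                RPPoint(0.5, 0.5, 0.5, 1),
                RPPoint(0.0, 0.9, None, 0),
            ],
        )
        assert fmax(curve) == pytest.approx(0.5)

    def test_fmax_empty_curve_errors(self):
        with pytest.raises(ValueError):
            fmax(RPCurve(measure="threshold", points=[]))

    def test_perfect_prediction_fmax_one_under_all_measures(self, forked):
        truth = {"t": {"a", "b", "c"}}
        preds = {"t": {"a": 1.0, "b": 1.0, "c": 1.0}}
        for curve_fn in (top20_curve, threshold_curve, leaf_threshold_curve):
            assert fmax(curve_fn(preds, truth, forked)) == 1.0


class TestRootExclusion:
    def test_root_in_prediction_never_counts(self, forked):
        truth = {"t": {"a"}}
        with_root = {"t": {"a": 1.0, "r": 1.0}}
        without = {"t": {"a": 1.0}}
        for curve_fn in (top20_curve, threshold_curve, leaf_threshold_curve):
            got = curve_fn(with_root, truth, forked).points
            want = curve_fn(without, truth, forked).points
            assert got == want


class TestRanking:
    def test_ties_share_better_rank(self):
        ranking = rank_methods({"m1": 0.36, "m2": 0.36, "m3": 0.34})
        assert ranking == [("m1", 0.36, 1), ("m2", 0.36, 1), ("m3", 0.34, 3)]

    def test_single_method(self):
        assert rank_methods({"only": 0.2}) == [("only", 0.2, 1)]

    def test_distinct_scores_strict_ordering(self):
        ranking = rank_methods({"a": 0.1, "b": 0.3, "c": 0.2})
        assert [r[0] for r in ranking] == ["b", "c", "a"]
        assert [r[2] for r in ranking] == [1, 2, 3]


def _naive_measures(preds, truths, graph):
    """Independent brute-force reimplementation of the three measures."""
    root = graph.root

    def prf(pairs):
        recs, precs = [], []
        for predicted, truth in pairs:
            correct = len(predicted & truth)
            recs.append(correct / len(truth))
            if predicted:
                precs.append(correct / len(predicted))
        return (
            sum(recs) / len(recs),
            (sum(precs) / len(precs)) if precs else None,
        )

    targets = sorted(truths)
    out = {"top20": [], "threshold": [], "leaf": []}
    for k in range(1, 21):
        pairs = []
        for t in targets:
            scores = {x: s for x, s in preds.get(t, {}).items() if x != root}
            distinct = sorted({s for s in scores.values()}, reverse=True)[:k]
            cut = min(distinct) if distinct else None
            chosen = (
                {x for x, s in scores.items() if s >= cut - 1e-9} if cut is not None else set()
            )
            pairs.append((chosen, truths[t] - {root}))
        out["top20"].append(prf(pairs))
    for i in range(100, -1, -1):
        thr = i / 100.0
        pairs, leaf_pairs = [], []
        for t in targets:
            scores = {x: s for x, s in preds.get(t, {}).items() if x != root}
            truth = truths[t] - {root}
            pairs.append(
                ({x for x, s in scores.items() if s >= thr - 1e-9}, truth)
            )
            pl = {x: s for x, s in scores.items() if x in leaf_terms(set(scores), graph)}
            leaf_pairs.append(
                (
                    {x for x, s in pl.items() if s >= thr - 1e-9},
                    leaf_terms(truth, graph),
                )
            )
        out["threshold"].append(prf(pairs))
        out["leaf"].append(prf(leaf_pairs))
    return out


@pytest.mark.parametrize("seed", range(4))
def test_measures_match_brute_force_on_random_instances(seed):
    rng = np.random.default_rng(300 + seed)
    graph = load_ontology(random_dag_edges(rng, 25))
    terms = sorted(graph.terms - {graph.root})
    truths = {}
    preds = {}
    for t in range(6):
        name = f"t{t}"
        truth_seed = {x for x in terms if rng.random() < 0.3} or {terms[0]}
        truths[name] = graph.propagate_membership(truth_seed) - {graph.root}
        if rng.random() < 0.85:  # some targets stay unpredicted
            raw = {x: round(float(rng.random()), 2) for x in terms if rng.random() < 0.4}
            if raw:
                prop = propagate_max(raw, graph)
                prop.pop(graph.root, None)
                preds[name] = prop
    naive = _naive_measures(preds, truths, graph)
    for label, curve_fn in (
        ("top20", top20_curve),
        ("threshold", threshold_curve),
        ("leaf", leaf_threshold_curve),
    ):
        curve = curve_fn(preds, truths, graph)
        assert len(curve) == len(naive[label])
        for pt, (rec, prec) in zip(curve.points, naive[label]):
            assert pt.recall == pytest.approx(rec)
            if prec is None:
                assert pt.precision is None
            else:
                assert pt.precision == pytest.approx(prec)
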