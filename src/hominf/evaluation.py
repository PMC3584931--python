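"""Recall-precision assessment of predicted GO annotations.

Three measures compare a scored, propagated prediction against the
propagated experimental annotation of each target (the root never
counts anywhere):

* top-20 — the prediction is grown tier by tier, where tier k keeps the
  terms whose score is among the k highest distinct reliabilities;
* threshold — the prediction is cut at reliability thresholds swept
  from 1.00 down to 0.00 in steps of 0.01;
* leaf threshold — both truth and prediction are first reduced to their
  leaf terms, then the same threshold sweep is applied to the predicted
  leaves. This measure rewards predicting the *exact* functions and
  penalizes bloated or over-general predictions.

Recall is macro-averaged over all targets (an unpredicted target
contributes recall 0); precision is averaged only over the targets with
a non-empty prediction at the current cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .ontology import OntologyGraph, TermId, leaf_terms

__all__ = [
    "RPPoint",
    "RPCurve",
    "top20_curve",
    "threshold_curve",
    "leaf_threshold_curve",
    "f1",
    "fmax",
    "rank_methods",
]

#: Tolerance on score >= threshold comparisons so that 3-decimal
#: prediction files hit 0.82-style boundaries deterministically.
_THRESH_EPS = 1e-9

Scores = Mapping[TermId, float]
TruthSets = Mapping[str, Set[TermId]]


@dataclass(frozen=True)
class RPPoint:
    control: float  # tier index or threshold
    recall: float
    precision: Optional[float]  # None when no target had a prediction
    n_predicted_targets: int


@dataclass
class RPCurve:
    measure: str  # "top20" | "threshold" | "leaf"
    points: List[RPPoint]

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)


def _strip_root(terms: Iterable[TermId], graph: OntologyGraph) -> Set[TermId]:
    return {t for t in terms if t != graph.root}


def _average_point(
    control: float,
    per_target: Sequence[Tuple[Set[TermId], Set[TermId]]],
) -> RPPoint:
    """Macro-average recall/precision over (predicted, truth) pairs."""
    recalls: List[float] = []
    precisions: List[float] = []
    for predicted, truth in per_target:
        correct = len(predicted & truth)
        recalls.append(correct / len(truth) if truth else 0.0)
        if predicted:
            precisions.append(correct / len(predicted))
    recall = sum(recalls) / len(recalls) if recalls else 0.0
    precision = sum(precisions) / len(precisions) if precisions else None
    return RPPoint(
        control=control,
        recall=recall,
        precision=precision,
        n_predicted_targets=len(precisions),
    )


def _prepared(
    preds: Mapping[str, Scores], truths: TruthSets, graph: OntologyGraph
) -> List[Tuple[Dict[TermId, float], Set[TermId]]]:
    """Pair each truth target with its (possibly empty) root-stripped scores."""
    out = []
    for target in sorted(truths):
        truth = _strip_root(truths[target], graph)
        if not truth:
            raise ValueError(f"empty truth annotation for target {target!r}")
        scores = preds.get(target, {})
        scores = {t: s for t, s in scores.items() if t != graph.root}
        out.append((scores, truth))
    return out


def top20_curve(
    preds: Mapping[str, Scores], truths: TruthSets, graph: OntologyGraph
) -> RPCurve:
    """Tiered measure: tier k keeps terms within the k highest distinct scores."""
    pairs = _prepared(preds, truths, graph)
    tiers = []
    for scores, truth in pairs:
        distinct = sorted(set(scores.values()), reverse=True)
        tiers.append((scores, distinct, truth))
    points = []
    for k in range(1, 21):
        per_target = []
        for scores, distinct, truth in tiers:
            if distinct:
                cut = distinct[min(k, len(distinct)) - 1]
                predicted = {t for t, s in scores.items() if s >= cut - _THRESH_EPS}
            else:
                predicted = set()
            per_target.append((predicted, truth))
        points.append(_average_point(float(k), per_target))
    return RPCurve(measure="top20", points=points)


def _threshold_sweep() -> List[float]:
    return [round(i / 100.0, 2) for i in range(100, -1, -1)]


def threshold_curve(
    preds: Mapping[str, Scores], truths: TruthSets, graph: OntologyGraph
) -> RPCurve:
    """Reliability-threshold sweep from 1.00 down to 0.00 (101 points)."""
    pairs = _prepared(preds, truths, graph)
    points = []
    for thr in _threshold_sweep():
        per_target = []
        for scores, truth in pairs:
            predicted = {t for t, s in scores.items() if s >= thr - _THRESH_EPS}
            per_target.append((predicted, truth))
        points.append(_average_point(thr, per_target))
    return RPCurve(measure="threshold", points=points)


def leaf_threshold_curve(
    preds: Mapping[str, Scores], truths: TruthSets, graph: OntologyGraph
) -> RPCurve:
    """Threshold sweep on the leaf terms of truth and prediction.

    The truth is reduced to its leaf terms once; the prediction is
    reduced to the leaves of its full propagation, and each threshold
    keeps the predicted leaves scoring at least the threshold.
    """
    pairs = _prepared(preds, truths, graph)
    reduced = []
    for scores, truth in pairs:
        truth_leaves = leaf_terms(truth, graph)
        pred_leaves = {t: scores[t] for t in leaf_terms(set(scores), graph)}
        reduced.append((pred_leaves, truth_leaves))
    points = []
    for thr in _threshold_sweep():
        per_target = []
        for pred_leaves, truth_leaves in reduced:
            predicted = {
                t for t, s in pred_leaves.items() if s >= thr - _THRESH_EPS
            }
            per_target.append((predicted, truth_leaves))
        points.append(_average_point(thr, per_target))
    return RPCurve(measure="leaf", points=points)


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def fmax(curve: RPCurve) -> float:
    """Maximum F1 over the curve's points with defined precision."""
    if len(curve) == 0:
        raise ValueError("empty recall-precision curve")
    best = 0.0
    for pt in curve:
        if pt.precision is not None:
            best = max(best, f1(pt.precision, pt.recall))
    return best


def rank_methods(fmax_by_method: Mapping[str, float]) -> List[Tuple[str, float, int]]:
    """Rank methods by descending Fmax with competition ranking.

    Tied methods share the better rank (1, 1, 3, ...); ties are listed
    alphabetically. Returns (method, fmax, rank) triples.
    """
    if not fmax_by_method:
        raise ValueError("no methods to rank")
    ordered = sorted(fmax_by_method.items(), key=lambda kv: (-kv[1], kv[0]))
    out: List[Tuple[str, float, int]] = []
    for i, (method, score) in enumerate(ordered):
        rank = 1 + sum(1 for _, s in ordered if s > score)
        out.append((method, score, rank))
    return out
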