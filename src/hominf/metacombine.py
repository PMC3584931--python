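"""Parameter-grid optimization and the least-squares meta-combiner.

Each student method exposes a small grid of option values (hit counts,
E-value cutoffs, search-iteration file, evidence filter, ...). The grid
is searched exhaustively for the configuration maximizing Fmax of the
threshold measure on a hold-out set. The three optimized methods are
then fused per predicted term by a weighted least-squares linear model
``p = x*A + y*B + z*C + i`` trained on out-of-fold predictions from a
two-fold split, so no target contributes training rows predicted with
parameters tuned on itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .annotations import AnnotationDB, HitTable, filter_experimental
from .evaluation import fmax, threshold_curve
from .ontology import OntologyGraph, TermId, propagate_max
from .predictors import (
    Prediction,
    PredictorParams,
    compile_background,
    predict_student_a,
    predict_student_b,
    predict_student_c,
)

__all__ = [
    "MetaModel",
    "enumerate_grid",
    "run_predictor",
    "optimize_params",
    "two_fold_predictions",
    "build_training_rows",
    "fit_meta",
    "predict_meta",
]

HitsByIteration = Mapping[int, Mapping[str, HitTable]]

_ITERATIONS = (1, 2, 3)
_EVIDENCE = (False, True)


def enumerate_grid(method: str) -> List[PredictorParams]:
    """Full Cartesian option grid of one method, in deterministic order.

    Cardinalities: A -> 36, B -> 54, C -> 72.
    """
    method = method.upper()
    grid: List[PredictorParams] = []
    if method == "A":
        for exclude_half, max_hits, iters, expo in itertools.product(
            (False, True), (1, 5, 9), _ITERATIONS, _EVIDENCE
        ):
            grid.append(
                PredictorParams(
                    method="A",
                    max_hits=max_hits,
                    max_evalue=0.1,
                    iterations=iters,
                    experimental_only=expo,
                    exclude_half_scores=exclude_half,
                )
            )
    elif method == "B":
        for max_evalue, max_hits, iters, expo in itertools.product(
            (1e0, 1e-3, 1e-6), (5, 50, 500), _ITERATIONS, _EVIDENCE
        ):
            grid.append(
                PredictorParams(
                    method="B",
                    max_hits=max_hits,
                    max_evalue=max_evalue,
                    iterations=iters,
                    experimental_only=expo,
                )
            )
    elif method == "C":
        for max_evalue, identity_kind, all_branches, iters, expo in itertools.product(
            (1e0, 1e-3, 1e-6), ("positives", "identity"), (False, True),
            _ITERATIONS, _EVIDENCE,
        ):
            grid.append(
                PredictorParams(
                    method="C",
                    max_evalue=max_evalue,
                    iterations=iters,
                    experimental_only=expo,
                    identity_kind=identity_kind,
                    all_branches=all_branches,
                )
            )
    else:
        raise ValueError(f"unknown method: {method!r}")
    return grid


def run_predictor(
    params: PredictorParams,
    graph: OntologyGraph,
    db: AnnotationDB,
    hits_by_iteration: HitsByIteration,
    targets: Sequence[str],
) -> Dict[str, Dict[TermId, float]]:
    """Predict every target under one parameter setting.

    ``params.iterations`` selects the hit file; ``experimental_only``
    filters the annotation database to experimental evidence codes.
    Targets without a hit table produce empty predictions.
    """
    tables = hits_by_iteration.get(params.iterations)
    if tables is None:
        raise ValueError(f"no hit tables for iteration setting {params.iterations}")
    used_db = filter_experimental(db) if params.experimental_only else db
    if len(used_db) == 0:
        return {t: {} for t in targets}
    background: Optional[List[float]] = None
    if params.method == "B":
        background = compile_background(tables, used_db, params)
    out: Dict[str, Dict[TermId, float]] = {}
    for target in targets:
        table = tables.get(target, HitTable(query=target, hits=[]))
        if params.method == "A":
            pred = predict_student_a(table, used_db, graph, params)
        elif params.method == "B":
            pred = predict_student_b(table, used_db, graph, params, background)
        elif params.method == "C":
            pred = predict_student_c(table, used_db, graph, params)
        else:
            raise ValueError(f"unknown method: {params.method!r}")
        out[target] = pred.scores
    return out


def optimize_params(
    method: str,
    graph: OntologyGraph,
    db: AnnotationDB,
    hits_by_iteration: HitsByIteration,
    targets: Sequence[str],
    truths: Mapping[str, Set[TermId]],
    grid: Optional[Sequence[PredictorParams]] = None,
) -> Tuple[PredictorParams, float]:
    """Exhaustive grid search maximizing threshold-measure Fmax.

    Returns the winning setting and its Fmax; ties keep the earliest
    setting in enumeration order.
    """
    settings = list(grid) if grid is not None else enumerate_grid(method)
    if not settings:
        raise ValueError("empty parameter grid")
    sub_truths = {t: truths[t] for t in targets}
    best: Optional[Tuple[PredictorParams, float]] = None
    for params in settings:
        preds = run_predictor(params, graph, db, hits_by_iteration, targets)
        score = fmax(threshold_curve(preds, sub_truths, graph))
        if best is None or score > best[1]:
            best = (params, score)
    return best


def two_fold_predictions(
    graph: OntologyGraph,
    db: AnnotationDB,
    hits_by_iteration: HitsByIteration,
    targets: Sequence[str],
    truths: Mapping[str, Set[TermId]],
    seed: int,
    methods: Sequence[str] = ("A", "B", "C"),
    grids: Optional[Mapping[str, Sequence[PredictorParams]]] = None,
) -> Dict[str, Dict[str, Dict[TermId, float]]]:
    """Out-of-fold predictions per method via a seeded two-fold split.

    Targets are shuffled and split into halves of floor(n/2) and
    ceil(n/2); parameters are optimized on one half and applied to the
    other, then the roles are switched, so every target is predicted
    exactly once per method with parameters tuned on the opposite fold.
    Returns ``{method: {target: scores}}``.
    """
    targets = list(targets)
    if len(targets) < 2:
        raise ValueError("two-fold protocol needs at least 2 targets")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(targets)))
    shuffled = [targets[i] for i in order]
    half = len(shuffled) // 2
    folds = (shuffled[:half], shuffled[half:])

    out: Dict[str, Dict[str, Dict[TermId, float]]] = {m: {} for m in methods}
    for train, test in ((folds[0], folds[1]), (folds[1], folds[0])):
        for method in methods:
            grid = grids.get(method) if grids else None
            params, _ = optimize_params(
                method, graph, db, hits_by_iteration, train, truths, grid
            )
            preds = run_predictor(params, graph, db, hits_by_iteration, test)
            out[method].update(preds)
    return out


@dataclass
class MetaModel:
    """Linear fusion model p = x*A + y*B + z*C + intercept."""

    x: float
    y: float
    z: float
    intercept: float
    rank: int = 4
    flagged: bool = False  # True when the design was rank-deficient

    @property
    def coefficients(self) -> Tuple[float, float, float, float]:
        return (self.x, self.y, self.z, self.intercept)


def build_training_rows(
    preds_a: Mapping[str, Mapping[TermId, float]],
    preds_b: Mapping[str, Mapping[TermId, float]],
    preds_c: Mapping[str, Mapping[TermId, float]],
    truths: Mapping[str, Set[TermId]],
    graph: OntologyGraph,
) -> List[Tuple[float, float, float, int]]:
    """One row per (target, candidate term): method scores and 0/1 label.

    Candidate terms are the union of the three methods' predictions for
    the target; a method that did not predict a term contributes 0.
    """
    rows: List[Tuple[float, float, float, int]] = []
    for target in sorted(truths):
        truth = truths[target] - {graph.root}
        a = preds_a.get(target, {})
        b = preds_b.get(target, {})
        c = preds_c.get(target, {})
        candidates = (set(a) | set(b) | set(c)) - {graph.root}
        for term in sorted(candidates):
            rows.append(
                (
                    a.get(term, 0.0),
                    b.get(term, 0.0),
                    c.get(term, 0.0),
                    1 if term in truth else 0,
                )
            )
    return rows


def fit_meta(
    rows: Sequence[Tuple[float, float, float, int]],
    weighting: str = "balanced",
) -> MetaModel:
    """Weighted least-squares fit of the fusion coefficients.

    ``balanced`` weighting gives the positive and negative label classes
    equal total weight (candidate-term rows are overwhelmingly
    negative); ``uniform`` weights every row equally. A rank-deficient
    design falls back to the minimum-norm solution and sets
    ``flagged``.
    """
    if len(rows) < 4:
        raise ValueError("need at least 4 training rows")
    arr = np.asarray(rows, dtype=float)
    X = np.column_stack([arr[:, :3], np.ones(len(arr))])
    y = arr[:, 3]
    if weighting == "balanced":
        n_pos = int(y.sum())
        n_neg = len(y) - n_pos
        w = np.ones(len(y))
        if n_pos and n_neg:
            w[y == 1] = len(y) / (2.0 * n_pos)
            w[y == 0] = len(y) / (2.0 * n_neg)
    elif weighting == "uniform":
        w = np.ones(len(y))
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return MetaModel(
        x=float(coef[0]),
        y=float(coef[1]),
        z=float(coef[2]),
        intercept=float(coef[3]),
        rank=int(rank),
        flagged=rank < 4,
    )


def predict_meta(
    model: MetaModel,
    preds_a: Mapping[TermId, float],
    preds_b: Mapping[TermId, float],
    preds_c: Mapping[TermId, float],
    graph: OntologyGraph,
    target: str = "",
) -> Prediction:
    """Fuse three per-term score sets into one prediction.

    Candidate terms are the union of the inputs; each is scored
    ``x*A + y*B + z*C + i`` (missing method score 0), clamped into
    [0, 1], then max-propagated with the root stripped.
    """
    candidates = (set(preds_a) | set(preds_b) | set(preds_c)) - {graph.root}
    scores: Dict[TermId, float] = {}
    for term in candidates:
        p = (
            model.x * preds_a.get(term, 0.0)
            + model.y * preds_b.get(term, 0.0)
            + model.z * preds_c.get(term, 0.0)
            + model.intercept
        )
        scores[term] = min(max(p, 0.0), 1.0)
    if not scores:
        return Prediction(target=target)
    out = propagate_max(scores, graph)
    out.pop(graph.root, None)
    return Prediction(target=target, scores=out)
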