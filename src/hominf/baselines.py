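"""Baseline GO-term predictors and the Priors-vs-Priors' coincidence model.

Four baselines contextualize the homology predictors:

* Priors — every target receives the whole set of database terms,
  scored by their database frequency;
* Priors' — each target receives the propagated annotation of one
  randomly drawn database protein, scored by the Priors frequencies;
* BLAST — per term, the best percent sequence identity among hits
  annotated with the term;
* GOtcha — per term, the summed negative log E-value (I-score) of the
  hits annotated with the term, normalized by the root's I-score.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .annotations import AnnotationDB, HitTable, log_evalue, term_frequencies
from .ontology import OntologyGraph, TermId, propagate_max
from .predictors import Prediction

__all__ = [
    "predict_priors",
    "predict_priors_random",
    "predict_blast_baseline",
    "predict_gotcha",
    "simulate_priors_coincidence",
]


def _strip_root(scores: Dict[TermId, float], graph: OntologyGraph) -> Dict[TermId, float]:
    scores = dict(scores)
    scores.pop(graph.root, None)
    return scores


def predict_priors(
    db: AnnotationDB, graph: OntologyGraph, target: str = ""
) -> Prediction:
    """Target-independent frequency prediction.

    Every term ever observed in the (propagated) database annotations is
    predicted, scored by the fraction of database proteins carrying it.
    """
    freqs = term_frequencies(db, graph)
    return Prediction(target=target, scores=_strip_root(freqs, graph))


def predict_priors_random(
    db: AnnotationDB,
    graph: OntologyGraph,
    rng: np.random.Generator,
    target: str = "",
) -> Prediction:
    """Annotation of one uniformly drawn database protein, Priors-scored."""
    if len(db) == 0:
        raise ValueError("empty annotation database")
    freqs = term_frequencies(db, graph)
    proteins = db.proteins
    pick = proteins[int(rng.integers(len(proteins)))]
    scores = {t: freqs[t] for t in db.propagated(pick, graph)}
    return Prediction(target=target, scores=_strip_root(scores, graph))


def predict_blast_baseline(
    hits: HitTable, db: AnnotationDB, graph: OntologyGraph
) -> Prediction:
    """Best percent identity over the hits annotated with each term."""
    scores: Dict[TermId, float] = {}
    for h in hits:
        terms = db.terms_of(h.subject)
        if not terms:
            continue
        for t in graph.propagate_membership(terms):
            scores[t] = max(scores.get(t, 0.0), h.percent_identity / 100.0)
    if not scores:
        return Prediction(target=hits.query)
    return Prediction(
        target=hits.query, scores=_strip_root(propagate_max(scores, graph), graph)
    )


def predict_gotcha(
    hits: HitTable, db: AnnotationDB, graph: OntologyGraph
) -> Prediction:
    """GOtcha I-scores, normalized per target by the root's I-score.

    I(t) = sum over hits annotated (after propagation) with t of
    -ln(E); E-values are clamped below 1 so every contribution is
    positive and the root accumulates the total, making the normalized
    scores monotone toward the root with root score exactly 1.
    """
    iscores: Dict[TermId, float] = {}
    for h in hits:
        terms = db.terms_of(h.subject)
        if not terms:
            continue
        weight = -log_evalue(h.evalue)
        for t in graph.propagate_membership(terms):
            iscores[t] = iscores.get(t, 0.0) + weight
    if not iscores:
        return Prediction(target=hits.query)
    root_score = iscores[graph.root]
    scores = {t: v / root_score for t, v in iscores.items()}
    return Prediction(target=hits.query, scores=_strip_root(scores, graph))


def simulate_priors_coincidence(
    p: float, n_targets: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo estimate of P(term picked AND term true) = p^2.

    Models why the random-protein baseline loses true positives relative
    to the all-terms baseline: a term of database frequency *p* is both
    picked by the random draw and actually true for the target only when
    two independent Bernoulli(p) events coincide.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    picked = rng.random(n_targets) < p
    true = rng.random(n_targets) < p
    return float(np.mean(picked & true))
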