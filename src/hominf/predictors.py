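"""Three nearest-neighbor GO-term predictors built on homology hit lists.

All three transfer annotations from the hits of a sequence search
against an annotated protein database, but differ in how hits are
scored and combined:

* ``student_a`` — binary consensus: a term present in the (propagated)
  annotation of every retained hit scores 1.0, otherwise 0.5, followed
  by a branch-overlap redundancy reduction.
* ``student_b`` — E-value weighted: a per-query template quality score
  (percentile of the hit list's log-E-value summary against a
  background) is multiplied with a per-leaf combined support score.
* ``student_c`` — count based: cumulative (summed) propagation of raw
  term counts, normalized at the root, times the best alignment
  identity of the supporting hits; outputs the branch of the top leaf.

Each predictor returns a propagated, monotone score set with the root
stripped; an empty hit table yields an empty prediction.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set

from .annotations import AnnotationDB, HitTable, filter_hits, log_evalue
from .ontology import (
    OntologyGraph,
    TermId,
    branch_of,
    branch_overlap,
    deepest_common_term,
    leaf_terms,
    propagate_cumulative,
    propagate_max,
)

__all__ = [
    "PredictorParams",
    "Prediction",
    "predict_student_a",
    "raw_template_score",
    "template_quality_score",
    "compile_background",
    "term_support",
    "combined_leaf_score",
    "predict_student_b",
    "predict_student_c",
]


@dataclass(frozen=True)
class PredictorParams:
    """Configuration of one student method.

    ``iterations`` does not run a search; it selects which precomputed
    hit file (one per search-iteration setting) feeds the predictor.
    """

    method: str  # "A", "B" or "C"
    max_hits: Optional[int] = None
    max_evalue: Optional[float] = None
    iterations: int = 2
    experimental_only: bool = False
    exclude_half_scores: bool = False  # A only
    identity_kind: str = "positives"  # C only: "positives" | "identity"
    all_branches: bool = False  # C only

    @staticmethod
    def default(method: str) -> "PredictorParams":
        """The original (pre-optimization) settings of each method."""
        method = method.upper()
        if method == "A":
            return PredictorParams(method="A", max_hits=6, max_evalue=0.1)
        if method == "B":
            return PredictorParams(method="B", max_hits=250, max_evalue=1e-2)
        if method == "C":
            return PredictorParams(method="C", max_hits=None, max_evalue=0.1)
        raise ValueError(f"unknown method: {method!r}")


@dataclass
class Prediction:
    """Scored GO terms of one target in one namespace (root stripped)."""

    target: str
    scores: Dict[TermId, float] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.scores)


def _finalize(target: str, scores: Mapping[TermId, float], graph: OntologyGraph) -> Prediction:
    """Propagate by max, clip to [0, 1] and strip the root."""
    out = propagate_max(scores, graph) if scores else {}
    out.pop(graph.root, None)
    return Prediction(target=target, scores={t: min(max(s, 0.0), 1.0) for t, s in out.items()})


def _retained_hits(hits: HitTable, db: AnnotationDB, params: PredictorParams) -> HitTable:
    """Shared hit pipeline: E-value cutoff, self-hit removal, drop
    subjects without annotations, then truncate to max_hits."""
    table = filter_hits(hits, max_evalue=params.max_evalue, max_hits=None)
    annotated = [h for h in table.hits if db.terms_of(h.subject)]
    if params.max_hits is not None:
        annotated = annotated[: params.max_hits]
    return HitTable(query=hits.query, hits=annotated)


# ---------------------------------------------------------------------------
# student A


def predict_student_a(
    hits: HitTable,
    db: AnnotationDB,
    graph: OntologyGraph,
    params: Optional[PredictorParams] = None,
) -> Prediction:
    """Consensus predictor with branch-overlap redundancy reduction.

    Terms found in the propagated annotation of every retained hit are
    scored 1.0, all other transferred terms 0.5 (optionally dropped).
    The propagated scores are reduced to leaves, leaf branches are
    clustered by single linkage at >= 10% pairwise overlap, each cluster
    keeps the deepest leaf, and near-duplicate branch pairs (> 90%
    overlap) contribute their lowest common term as a correction.
    """
    params = params or PredictorParams.default("A")
    retained = _retained_hits(hits, db, params)
    if len(retained) == 0:
        return Prediction(target=hits.query)

    hit_props = [db.propagated(h.subject, graph) for h in retained]
    direct_terms: Set[TermId] = set()
    for h in retained:
        direct_terms |= db.terms_of(h.subject)

    scores: Dict[TermId, float] = {}
    for term in direct_terms:
        in_all = all(term in prop for prop in hit_props)
        scores[term] = 1.0 if in_all else 0.5
    if params.exclude_half_scores:
        scores = {t: s for t, s in scores.items() if s == 1.0}
    if not scores:
        return Prediction(target=hits.query)

    prop = propagate_max(scores, graph)
    leaves = sorted(leaf_terms(prop, graph))
    branches = {leaf: branch_of(leaf, graph) for leaf in leaves}

    # single-linkage clustering: join leaves whose branches overlap >= 10%
    parent = {leaf: leaf for leaf in leaves}

    def find(x: TermId) -> TermId:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, li in enumerate(leaves):
        for lj in leaves[i + 1 :]:
            if branch_overlap(branches[li], branches[lj]) >= 0.10:
                parent[find(li)] = find(lj)

    clusters: Dict[TermId, List[TermId]] = {}
    for leaf in leaves:
        clusters.setdefault(find(leaf), []).append(leaf)

    kept: Dict[TermId, float] = {}
    for members in clusters.values():
        best = min(members, key=lambda t: (-graph.depth(t), t))
        kept[best] = prop[best]

    # correction: highly redundant branch pairs re-inject their deepest
    # common term (scored with the better of the two leaf scores)
    for i, li in enumerate(leaves):
        for lj in leaves[i + 1 :]:
            if branch_overlap(branches[li], branches[lj]) > 0.90:
                common = deepest_common_term(branches[li], branches[lj], graph)
                score = max(prop[li], prop[lj])
                kept[common] = max(kept.get(common, 0.0), score)

    return _finalize(hits.query, kept, graph)


# ---------------------------------------------------------------------------
# student B


def raw_template_score(hits: HitTable) -> float:
    """Summary of a hit list's log E-values: mean(ln E) + 2 * sd(ln E).

    The sample standard deviation (n - 1 denominator) is used and is 0
    for a single hit. Lower (more negative) values indicate a more
    trustworthy hit list.
    """
    if len(hits) == 0:
        raise ValueError("raw template score requires at least one hit")
    logs = [log_evalue(h.evalue) for h in hits]
    mean = statistics.fmean(logs)
    sd = statistics.stdev(logs) if len(logs) > 1 else 0.0
    return mean + 2.0 * sd


def template_quality_score(raw: float, background: Sequence[float]) -> float:
    """Percentile-map a raw template score against a background sample.

    TQS = 1 - (fraction of background scores <= raw), so a raw score
    lower than the entire background maps to 1.0 and a score reached by
    90% of the background maps to 0.1.
    """
    if len(background) == 0:
        raise ValueError("empty background distribution")
    frac = sum(1 for b in background if b <= raw) / len(background)
    return min(max(1.0 - frac, 0.0), 1.0)


def compile_background(
    hit_tables: Mapping[str, HitTable],
    db: AnnotationDB,
    params: PredictorParams,
    sample: Optional[Sequence[str]] = None,
) -> List[float]:
    """Raw template scores over a sample of queries' hit tables.

    By default every provided table is used; *sample* restricts to a
    subset of query accessions. Queries whose filtered table is empty
    are skipped. Returns a sorted list.
    """
    queries = list(sample) if sample is not None else sorted(hit_tables)
    scores: List[float] = []
    for q in queries:
        table = hit_tables.get(q)
        if table is None:
            continue
        retained = _retained_hits(table, db, params)
        if len(retained):
            scores.append(raw_template_score(retained))
    return sorted(scores)


def term_support(
    term: TermId,
    hits: HitTable,
    db: AnnotationDB,
    graph: OntologyGraph,
) -> float:
    """Fraction of the hit list's log-E-value mass carried by *term*.

    sum of ln(E) over hits whose propagated annotation contains the
    term, divided by the sum over all hits. Both sums are negative, so
    the ratio lies in (0, 1]; a term absent from every hit scores 0.
    """
    if len(hits) == 0:
        raise ValueError("term support requires at least one hit")
    total = 0.0
    carried = 0.0
    for h in hits:
        lg = log_evalue(h.evalue)
        total += lg
        if term in db.propagated(h.subject, graph):
            carried += lg
    if carried == 0.0:
        return 0.0
    return carried / total


def combined_leaf_score(
    leaf: TermId,
    supports: Mapping[TermId, float],
    graph: OntologyGraph,
) -> float:
    """Mean support of a leaf and its ancestors, root excluded.

    The root's support is 1.0 by construction and the root never enters
    any evaluation, so including it would only inflate every score.
    """
    terms = [leaf] + [a for a in graph.ancestors(leaf) if a != graph.root]
    return statistics.fmean(supports.get(t, 0.0) for t in terms)


def predict_student_b(
    hits: HitTable,
    db: AnnotationDB,
    graph: OntologyGraph,
    params: Optional[PredictorParams] = None,
    background: Optional[Sequence[float]] = None,
) -> Prediction:
    """E-value weighted predictor: TQS x combined leaf score per leaf.

    *background* is the sorted raw-template-score sample used for the
    percentile mapping (see :func:`compile_background`); without one the
    template quality score defaults to 1.0 (pure leaf-score ranking).
    """
    params = params or PredictorParams.default("B")
    retained = _retained_hits(hits, db, params)
    if len(retained) == 0:
        return Prediction(target=hits.query)

    if background:
        tqs = template_quality_score(raw_template_score(retained), background)
    else:
        tqs = 1.0

    prop_terms: Set[TermId] = set()
    for h in retained:
        prop_terms |= db.propagated(h.subject, graph)
    supports = {t: term_support(t, retained, db, graph) for t in prop_terms}

    leaves = leaf_terms(prop_terms, graph)
    leaf_scores = {
        leaf: tqs * combined_leaf_score(leaf, supports, graph) for leaf in leaves
    }
    return _finalize(hits.query, leaf_scores, graph)


# ---------------------------------------------------------------------------
# student C


def predict_student_c(
    hits: HitTable,
    db: AnnotationDB,
    graph: OntologyGraph,
    params: Optional[PredictorParams] = None,
) -> Prediction:
    """Count-based predictor with cumulative propagation.

    Raw occurrences of each directly annotated term across the retained
    hits are propagated cumulatively (summed into ancestors, normalized
    at the root), then multiplied per term by the best alignment
    identity (percent positives by default) among the hits supporting
    the term. By default only the branch of the highest-scoring leaf is
    emitted; ``all_branches`` emits every leaf branch.
    """
    params = params or PredictorParams.default("C")
    retained = _retained_hits(hits, db, params)
    if len(retained) == 0:
        return Prediction(target=hits.query)

    counts: Dict[TermId, float] = {}
    for h in retained:
        for t in db.terms_of(h.subject):
            counts[t] = counts.get(t, 0.0) + 1.0
    cumulative = propagate_cumulative(counts, graph)

    identity: Dict[TermId, float] = {}
    for h in retained:
        pct = (
            h.percent_positives
            if params.identity_kind == "positives"
            else h.percent_identity
        )
        for t in db.propagated(h.subject, graph):
            identity[t] = max(identity.get(t, 0.0), pct / 100.0)

    scored = {t: cumulative[t] * identity.get(t, 0.0) for t in cumulative}
    leaves = sorted(leaf_terms(set(cumulative), graph))
    if not leaves:
        return Prediction(target=hits.query)

    if params.all_branches:
        chosen = leaves
    else:
        best = min(leaves, key=lambda t: (-scored[t], t))
        chosen = [best]

    out: Dict[TermId, float] = {}
    for leaf in chosen:
        for t in branch_of(leaf, graph):
            out[t] = max(out.get(t, 0.0), scored[t])
    return _finalize(hits.query, out, graph)
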