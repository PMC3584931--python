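"""Synthetic ontologies, annotation databases and homology hit tables.

The generators emulate the moving parts of a homology-based function
prediction study without any external downloads: a single-rooted random
DAG stands in for a GO namespace, a table of proteins annotated with
random leaf terms stands in for an annotated sequence database, and hit
tables with E-values anti-correlated with annotation overlap stand in
for a PSI-BLAST search against that database. Sequence content itself
is never simulated — the predictors consume only tabular alignment
statistics, so generating those directly is sufficient.

All generators are fully deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .annotations import AnnotationDB, AnnotationRecord, HitRecord, HitTable
from .ontology import OntologyGraph, TermId, load_ontology

__all__ = [
    "SimConfig",
    "Benchmark",
    "gen_ontology",
    "gen_annotation_db",
    "gen_hit_table",
    "gen_benchmark",
    "single_target_example",
]

#: Default evidence-code mix: roughly Swiss-Prot-like, two thirds
#: experimental codes and one third electronic (IEA) annotation.
DEFAULT_EVIDENCE_MIX: Dict[str, float] = {
    "IDA": 0.25,
    "IMP": 0.10,
    "IPI": 0.05,
    "IGI": 0.04,
    "IEP": 0.03,
    "TAS": 0.12,
    "IC": 0.03,
    "EXP": 0.05,
    "IEA": 0.33,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic benchmark.

    fidelity is the degree to which hit sampling favors database
    proteins sharing the target's annotation: 0 gives annotation-blind
    hits, 1 gives hits restricted to proteins carrying the full truth
    (with such perfect homologs planted into the template set).
    """

    seed: int
    n_terms: int = 60
    depth: int = 5
    branching: int = 3
    diamond_rate: float = 0.1
    n_proteins: int = 80
    target_fraction: float = 0.2
    max_annotation_leaves: int = 3
    evidence_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVIDENCE_MIX)
    )
    hits_per_target: int = 8
    log10_evalue_range: Tuple[float, float] = (-50.0, -0.5)
    evalue_noise_sd: float = 2.0  # log10 units
    fidelity: float = 0.9
    identity_noise_sd: float = 5.0  # percentage points


def _term_id(i: int) -> TermId:
    return f"GO:{i:07d}"


def gen_ontology(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> OntologyGraph:
    """Random single-rooted DAG built level by level.

    Level 0 holds the root; each further level (up to ``depth``) grows
    by the branching factor until ``n_terms`` nodes exist. Every node
    gets one ``is_a`` parent on the previous level; with probability
    ``diamond_rate`` a second ``part_of`` parent from any strictly
    shallower level is added (acyclic by construction).
    """
    if cfg.n_terms < 2:
        raise ValueError("need at least 2 terms (root + 1)")
    if cfg.depth < 1 or cfg.branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    levels: List[List[TermId]] = [[_term_id(1)]]
    next_id = 2
    remaining = cfg.n_terms - 1
    for level in range(1, cfg.depth + 1):
        if remaining <= 0:
            break
        width = min(len(levels[-1]) * cfg.branching, remaining)
        levels.append([_term_id(i) for i in range(next_id, next_id + width)])
        next_id += width
        remaining -= width
    if remaining > 0:
        raise ValueError(
            f"shape infeasible: depth {cfg.depth} x branching {cfg.branching} "
            f"cannot host {cfg.n_terms} terms"
        )
    edges: List[Tuple[str, str, str]] = []
    for level in range(1, len(levels)):
        for node in levels[level]:
            parent = levels[level - 1][int(rng.integers(len(levels[level - 1])))]
            edges.append((node, parent, "is_a"))
            if cfg.diamond_rate > 0 and rng.random() < cfg.diamond_rate:
                shallow = [t for lv in levels[:level] for t in lv if t != parent]
                if shallow:
                    extra = shallow[int(rng.integers(len(shallow)))]
                    edges.append((node, extra, "part_of"))
    return load_ontology(edges, namespace="SIM")


def _graph_leaves(graph: OntologyGraph) -> List[TermId]:
    return sorted(t for t in graph.terms if not graph.children(t))


def _draw_evidence(mix: Mapping[str, float], rng: np.random.Generator) -> str:
    codes = sorted(mix)
    probs = np.array([mix[c] for c in codes], dtype=float)
    probs = probs / probs.sum()
    return codes[int(rng.choice(len(codes), p=probs))]


def gen_annotation_db(
    graph: OntologyGraph,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    prefix: str = "P",
) -> AnnotationDB:
    """Annotate ``n_proteins`` proteins with 1..k random ontology leaves.

    Evidence codes are drawn independently per record from the
    configured mix.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    leaves = _graph_leaves(graph)
    records: List[AnnotationRecord] = []
    for i in range(cfg.n_proteins):
        protein = f"{prefix}{i:05d}"
        k = int(rng.integers(1, cfg.max_annotation_leaves + 1))
        k = min(k, len(leaves))
        picks = rng.choice(len(leaves), size=k, replace=False)
        for j in sorted(int(p) for p in picks):
            records.append(
                AnnotationRecord(protein, leaves[j], _draw_evidence(cfg.evidence_mix, rng))
            )
    return AnnotationDB(records=records)


def gen_hit_table(
    target: str,
    target_truth: Set[TermId],
    db: AnnotationDB,
    graph: OntologyGraph,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    n_hits: Optional[int] = None,
) -> HitTable:
    """Homology hits for one target, overlap-weighted by fidelity.

    Subjects are drawn without replacement with probability proportional
    to ``(1 - fidelity) + fidelity * overlap`` where overlap is the
    Jaccard-style fraction of the target truth covered by the subject's
    propagated annotation. At fidelity 1.0 only subjects carrying the
    complete truth are eligible (falling back to maximal overlap).
    E-values are log-uniform over the configured range, shifted toward
    significance for high-overlap subjects; percent positives rise with
    overlap and dominate percent identity.
    """
    if len(db) == 0:
        raise ValueError("empty template database")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    n_hits = n_hits if n_hits is not None else cfg.hits_per_target
    truth = {t for t in target_truth if t != graph.root}
    proteins = db.proteins
    overlaps = np.array(
        [
            len((db.propagated(p, graph) - {graph.root}) & truth) / max(len(truth), 1)
            for p in proteins
        ]
    )
    if cfg.fidelity >= 1.0:
        eligible = np.flatnonzero(overlaps >= 1.0 - 1e-12)
        if eligible.size == 0:
            eligible = np.flatnonzero(overlaps >= overlaps.max() - 1e-12)
        weights = np.zeros(len(proteins))
        weights[eligible] = 1.0
    else:
        weights = (1.0 - cfg.fidelity) + cfg.fidelity * overlaps
    total = weights.sum()
    if total <= 0:
        weights = np.ones(len(proteins))
        total = weights.sum()
    n = min(n_hits, int(np.count_nonzero(weights)))
    idx = rng.choice(len(proteins), size=n, replace=False, p=weights / total)

    lo, hi = cfg.log10_evalue_range
    hits: List[HitRecord] = []
    for i in idx:
        ov = overlaps[int(i)]
        log10e = lo + (1.0 - ov) * (hi - lo)
        if cfg.evalue_noise_sd > 0:
            log10e += float(rng.normal(0.0, cfg.evalue_noise_sd))
        log10e = float(min(max(log10e, -180.0), 2.0))
        evalue = 10.0**log10e
        ppos = 50.0 + 50.0 * ov
        if cfg.identity_noise_sd > 0:
            ppos += float(rng.normal(0.0, cfg.identity_noise_sd))
        ppos = float(min(max(ppos, 1.0), 100.0))
        pident = ppos
        if cfg.identity_noise_sd > 0:
            pident = ppos - abs(float(rng.normal(0.0, cfg.identity_noise_sd)))
        pident = float(min(max(pident, 0.0), ppos))
        length = int(rng.integers(80, 400))
        bitscore = float(max(25.0, 25.0 - 2.0 * log10e))
        hits.append(
            HitRecord(
                query=target,
                subject=proteins[int(i)],
                percent_identity=round(pident, 1),
                percent_positives=round(ppos, 1),
                align_length=length,
                evalue=evalue,
                bitscore=round(bitscore, 1),
            )
        )
    return HitTable(query=target, hits=hits)


@dataclass
class Benchmark:
    """A self-contained template/target evaluation scenario."""

    config: SimConfig
    graph: OntologyGraph
    db: AnnotationDB  # template proteins only
    targets: List[str]
    truths: Dict[str, Set[TermId]]  # propagated, root-stripped
    hits_by_iteration: Dict[int, Dict[str, HitTable]]


def gen_benchmark(cfg: SimConfig, iterations: Sequence[int] = (1, 2, 3)) -> Benchmark:
    """Generate a full benchmark: ontology, template DB, targets, hits.

    Proteins are split into disjoint template and target sets (the
    logical analogue of a temporal annotation split); the targets'
    annotations become the withheld truths and never enter the template
    database. One hit table per target is generated for each search
    iteration setting, later iterations returning a few extra hits. At
    fidelity 1.0, perfect-homolog templates (clones of each target's
    annotation) are planted so ideal inference is achievable.
    """
    rng = np.random.default_rng(cfg.seed)
    graph = gen_ontology(cfg, rng)
    full_db = gen_annotation_db(graph, cfg, rng)
    proteins = full_db.proteins
    n_targets = max(1, round(cfg.n_proteins * cfg.target_fraction))
    if n_targets >= len(proteins):
        raise ValueError("target fraction leaves no template proteins")
    picks = set(
        int(i) for i in rng.choice(len(proteins), size=n_targets, replace=False)
    )
    target_names = [proteins[i] for i in sorted(picks)]
    template_names = [p for i, p in enumerate(proteins) if i not in picks]

    truths = {
        t: full_db.propagated(t, graph) - {graph.root} for t in target_names
    }
    records = [r for r in full_db.records if r.protein in set(template_names)]
    if cfg.fidelity >= 1.0:
        for ti, target in enumerate(target_names):
            for j in range(cfg.hits_per_target):
                clone = f"H{ti:03d}_{j:02d}"
                for term in sorted(full_db.terms_of(target)):
                    records.append(
                        AnnotationRecord(
                            clone, term, _draw_evidence(cfg.evidence_mix, rng)
                        )
                    )
    db = AnnotationDB(records=records)

    hits_by_iteration: Dict[int, Dict[str, HitTable]] = {}
    for it in iterations:
        tables: Dict[str, HitTable] = {}
        for target in target_names:
            tables[target] = gen_hit_table(
                target,
                truths[target],
                db,
                graph,
                cfg,
                rng,
                n_hits=cfg.hits_per_target + 2 * (it - 1),
            )
        hits_by_iteration[it] = tables
    return Benchmark(
        config=cfg,
        graph=graph,
        db=db,
        targets=target_names,
        truths=truths,
        hits_by_iteration=hits_by_iteration,
    )


def single_target_example():
    """A hand-sized single-target instance for walking the measures.

    The ontology is a root with three chains of depths 4/4/5 plus one
    extra child ``x`` of the top term. The experimental annotation holds
    11 non-root terms with exactly 3 leaf terms; the prediction's top
    reliability tier (0.8) holds two terms of which one is experimental,
    and the prediction's only leaf above 0.8 is not an experimental
    leaf. Returns ``(graph, truths, predictions)`` for target ``"A"``.
    """
    edges = [
        ("a", "ROOT", "is_a"),
        ("b", "a", "is_a"),
        ("c", "b", "is_a"),
        ("d", "c", "is_a"),
        ("e", "a", "is_a"),
        ("f", "e", "is_a"),
        ("g", "f", "is_a"),
        ("h", "a", "is_a"),
        ("i", "h", "is_a"),
        ("j", "i", "is_a"),
        ("k", "j", "is_a"),
        ("x", "a", "is_a"),
    ]
    graph = load_ontology(edges, namespace="TOY")
    truths = {"A": {"a", "b", "c", "d", "e", "f", "g", "h", "i", "j", "k"}}
    predictions = {"A": {"a": 0.8, "x": 0.8, "b": 0.6, "e": 0.6}}
    return graph, truths, predictions
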