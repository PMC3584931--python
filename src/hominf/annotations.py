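"""Annotation databases and homology hit tables.

The annotation database maps proteins to directly annotated GO terms
with evidence codes (GAF-like three-column TSV). Hit tables are BLAST
tabular records (outfmt "6 qseqid sseqid pident ppos length evalue
bitscore") describing homologs of a query, ordered by E-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import pandas as pd

from .ontology import OntologyGraph, TermId, UnknownTermError

__all__ = [
    "EXPERIMENTAL_EVIDENCE_CODES",
    "AnnotationRecord",
    "AnnotationDB",
    "HitRecord",
    "HitTable",
    "load_annotations",
    "filter_experimental",
    "term_frequencies",
    "load_hits",
    "filter_hits",
    "log_evalue",
]

#: GO evidence codes counted as experimental support.
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"IDA", "IMP", "IPI", "IGI", "IEP", "TAS", "IC", "EXP"}
)

# E-value handling before taking logarithms: zero is floored so the log is
# finite, and values >= 1 are clamped below 1 so every log is strictly
# negative (keeps support ratios and GOtcha I-scores well-behaved).
_EVALUE_FLOOR = 1e-180
_EVALUE_CEIL = 0.999


def log_evalue(evalue: float) -> float:
    """Natural log of an E-value clamped into [1e-180, 0.999]."""
    return math.log(min(max(evalue, _EVALUE_FLOOR), _EVALUE_CEIL))


@dataclass(frozen=True)
class AnnotationRecord:
    protein: str
    term: TermId
    evidence: str


@dataclass
class AnnotationDB:
    """Deduplicated protein -> GO annotations with evidence codes."""

    records: List[AnnotationRecord]
    index: Dict[str, Set[TermId]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {}
            for rec in self.records:
                self.index.setdefault(rec.protein, set()).add(rec.term)

    @property
    def proteins(self) -> List[str]:
        return sorted(self.index)

    def __len__(self) -> int:
        return len(self.index)

    def terms_of(self, protein: str) -> Set[TermId]:
        """Directly annotated terms of *protein* (empty set if unknown)."""
        return set(self.index.get(protein, set()))

    def propagated(self, protein: str, graph: OntologyGraph) -> Set[TermId]:
        """True-path closure of the protein's direct annotation."""
        return graph.propagate_membership(self.index.get(protein, set()))


def _dedupe(records: Iterable[AnnotationRecord]) -> List[AnnotationRecord]:
    seen: Set[tuple] = set()
    out: List[AnnotationRecord] = []
    for rec in records:
        key = (rec.protein, rec.term)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def load_annotations(
    path,
    graph: Optional[OntologyGraph] = None,
    strict: bool = False,
) -> AnnotationDB:
    """Read a protein/term/evidence TSV into an :class:`AnnotationDB`.

    Lines starting with ``#`` are ignored. Duplicate (protein, term)
    pairs keep the first record. When *graph* is given, records whose
    term is absent from the ontology are dropped (or raise, if
    *strict*).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype=str, skip_blank_lines=True
    )
    if df.shape[1] < 3:
        raise ValueError("annotation file needs >= 3 columns (protein, term, evidence)")
    if df.iloc[:, :3].isna().any().any():
        raise ValueError("malformed annotation rows (missing fields)")
    records = [
        AnnotationRecord(p, t, e)
        for p, t, e in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
    ]
    if not all(r.evidence for r in records):
        raise ValueError("empty evidence code")
    if graph is not None:
        unknown = sorted({r.term for r in records if r.term not in graph})
        if unknown:
            if strict:
                raise UnknownTermError(
                    f"{len(unknown)} annotation term(s) not in ontology, "
                    f"e.g. {unknown[:3]}"
                )
            records = [r for r in records if r.term in graph]
    if not records:
        raise ValueError("no usable annotation records")
    return AnnotationDB(records=_dedupe(records))


def filter_experimental(
    db: AnnotationDB, codes: Iterable[str] = EXPERIMENTAL_EVIDENCE_CODES
) -> AnnotationDB:
    """Keep only records whose evidence code is in *codes*.

    Defaults to the eight experimental GO evidence codes (IDA, IMP, IPI,
    IGI, IEP, TAS, IC, EXP). The result may be empty.
    """
    codes = set(codes)
    if not codes:
        raise ValueError("evidence code set must be non-empty")
    return AnnotationDB(records=[r for r in db.records if r.evidence in codes])


def term_frequencies(db: AnnotationDB, graph: OntologyGraph) -> Dict[TermId, float]:
    """Database frequency of each term over propagated protein annotations.

    frequency(t) = (# proteins whose propagated annotation contains t)
    divided by the number of proteins; the root's frequency is 1.0.
    """
    if len(db) == 0:
        raise ValueError("empty annotation database")
    counts: Dict[TermId, int] = {}
    for protein in db.index:
        for t in db.propagated(protein, graph):
            counts[t] = counts.get(t, 0) + 1
    n = len(db)
    return {t: c / n for t, c in counts.items()}


@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    percent_identity: float
    percent_positives: float
    align_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue}")
        for pct in (self.percent_identity, self.percent_positives):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"percentage out of [0,100]: {pct}")


@dataclass
class HitTable:
    """Hits of one query, sorted by ascending E-value (ties keep input order)."""

    query: str
    hits: List[HitRecord]

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=lambda h: h.evalue)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)


_HIT_COLUMNS = ["qseqid", "sseqid", "pident", "ppos", "length", "evalue", "bitscore"]


def load_hits(path) -> List[HitTable]:
    """Parse a BLAST tabular file into one :class:`HitTable` per query.

    Expected columns: qseqid sseqid pident ppos length evalue bitscore.
    ``#`` comment lines are tolerated; an empty file yields an empty list.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < len(_HIT_COLUMNS):
        raise ValueError(
            f"hit table needs {len(_HIT_COLUMNS)} columns: {' '.join(_HIT_COLUMNS)}"
        )
    df = df.iloc[:, : len(_HIT_COLUMNS)]
    df.columns = _HIT_COLUMNS
    try:
        records = [
            HitRecord(
                query=row.qseqid,
                subject=row.sseqid,
                percent_identity=float(row.pident),
                percent_positives=float(row.ppos),
                align_length=int(row.length),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
            )
            for row in df.itertuples(index=False)
        ]
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed numeric field in hit table: {exc}") from exc
    tables: Dict[str, List[HitRecord]] = {}
    for rec in records:
        tables.setdefault(rec.query, []).append(rec)
    return [HitTable(query=q, hits=hs) for q, hs in tables.items()]


def filter_hits(
    table: HitTable,
    max_evalue: Optional[float] = None,
    max_hits: Optional[int] = None,
    exclude_self: bool = True,
) -> HitTable:
    """Apply the standard hit filter: strict E-value cutoff, self-hit
    removal, then truncation to the best *max_hits* records.

    The E-value comparison is strict (``evalue < max_evalue``) and the
    truncation happens after the cutoff. Idempotent for fixed parameters.
    """
    hits = list(table.hits)
    if max_evalue is not None:
        if max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        hits = [h for h in hits if h.evalue < max_evalue]
    if exclude_self:
        hits = [h for h in hits if h.subject != table.query]
    if max_hits is not None:
        if max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        hits = hits[:max_hits]
    return HitTable(query=table.query, hits=hits)
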