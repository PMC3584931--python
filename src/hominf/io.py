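"""Plain-text readers and writers for every format the toolkit touches.

All tables are tab-separated; ``#`` lines are comments. Writers go
through a temporary file and an atomic rename so partial outputs never
appear under the final name.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Set

import obonet
import pandas as pd

from .annotations import AnnotationDB, HitTable
from .metacombine import MetaModel
from .evaluation import RPCurve, f1
from .ontology import OntologyGraph, TermId, load_ontology

__all__ = [
    "read_ontology_tsv",
    "write_ontology_tsv",
    "read_obo",
    "write_annotations",
    "write_hits",
    "read_predictions",
    "write_predictions",
    "read_truth",
    "write_truth",
    "write_curve",
    "read_meta_model",
    "write_meta_model",
]


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_ontology_tsv(path, namespace: str = "GO") -> OntologyGraph:
    """Load child/parent/relation TSV into a validated ontology."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ontology file needs columns: child, parent[, relation]")
    if df.shape[1] == 2:
        df[2] = "is_a"
    edges = [(r[0], r[1], r[2]) for r in df.itertuples(index=False)]
    return load_ontology(edges, namespace=namespace)


def write_ontology_tsv(graph: OntologyGraph, path) -> None:
    lines = ["#child\tparent\trelation"]
    for child, parent, data in sorted(graph.graph.edges(data=True)):
        lines.append(f"{child}\t{parent}\t{data.get('relation', 'is_a')}")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_obo(path, namespace: Optional[str] = None) -> OntologyGraph:
    """Minimal OBO support: id / is_a / relationship: part_of stanzas.

    When *namespace* is given, only stanzas of that GO namespace are
    kept (the ontology must still resolve to a single root).
    """
    g = obonet.read_obo(path)
    edges = []
    for child, parent, key in g.edges(keys=True):
        if key not in ("is_a", "part_of"):
            continue
        if namespace is not None:
            if g.nodes[child].get("namespace") not in (None, namespace):
                continue
            if g.nodes[parent].get("namespace") not in (None, namespace):
                continue
        edges.append((child, parent, key))
    return load_ontology(edges, namespace=namespace or "GO")


def write_annotations(db: AnnotationDB, path) -> None:
    lines = ["#protein\tterm\tevidence"]
    for rec in db.records:
        lines.append(f"{rec.protein}\t{rec.term}\t{rec.evidence}")
    _atomic_write(path, "\n".join(lines) + "\n")


def write_hits(tables: Iterable[HitTable], path) -> None:
    lines = ["#qseqid\tsseqid\tpident\tppos\tlength\tevalue\tbitscore"]
    for table in tables:
        for h in table:
            lines.append(
                f"{h.query}\t{h.subject}\t{h.percent_identity:g}\t"
                f"{h.percent_positives:g}\t{h.align_length}\t{h.evalue:.3g}\t"
                f"{h.bitscore:g}"
            )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_predictions(path) -> Dict[str, Dict[TermId, float]]:
    """CAFA-style prediction TSV (target, term, score) -> nested dict."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    if df.shape[1] < 3:
        raise ValueError("prediction file needs columns: target, term, score")
    out: Dict[str, Dict[TermId, float]] = {}
    for target, term, score in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        out.setdefault(target, {})[term] = float(score)
    return out


def write_predictions(
    preds: Mapping[str, Mapping[TermId, float]], path, decimals: int = 3
) -> None:
    lines = ["#target\tterm\tscore"]
    for target in sorted(preds):
        for term in sorted(preds[target]):
            lines.append(f"{target}\t{term}\t{preds[target][term]:.{decimals}f}")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_truth(path) -> Dict[str, Set[TermId]]:
    """Truth TSV (target, term); terms are the propagated annotation."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("truth file needs columns: target, term")
    out: Dict[str, Set[TermId]] = {}
    for target, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(target, set()).add(term)
    return out


def write_truth(truths: Mapping[str, Set[TermId]], path) -> None:
    lines = ["#target\tterm"]
    for target in sorted(truths):
        for term in sorted(truths[target]):
            lines.append(f"{target}\t{term}")
    _atomic_write(path, "\n".join(lines) + "\n")


def write_curve(curve: RPCurve, path) -> None:
    """Curve TSV: control, recall, precision, f1 (blank when undefined)."""
    lines = ["#control\trecall\tprecision\tf1"]
    for pt in curve:
        if pt.precision is None:
            lines.append(f"{pt.control:g}\t{pt.recall:.4f}\t\t")
        else:
            lines.append(
                f"{pt.control:g}\t{pt.recall:.4f}\t{pt.precision:.4f}\t"
                f"{f1(pt.precision, pt.recall):.4f}"
            )
    _atomic_write(path, "\n".join(lines) + "\n")


def write_meta_model(model: MetaModel, path) -> None:
    text = (
        f"x\t{model.x:.6f}\ny\t{model.y:.6f}\nz\t{model.z:.6f}\n"
        f"intercept\t{model.intercept:.6f}\nrank\t{model.rank}\n"
        f"flagged\t{int(model.flagged)}\n"
    )
    _atomic_write(path, text)


def read_meta_model(path) -> MetaModel:
    values: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, val = line.split("\t")
        values[key] = val
    return MetaModel(
        x=float(values["x"]),
        y=float(values["y"]),
        z=float(values["z"]),
        intercept=float(values["intercept"]),
        rank=int(values.get("rank", 4)),
        flagged=bool(int(values.get("flagged", 0))),
    )
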