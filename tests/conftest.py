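import numpy as np
import pytest

from hominf import (
    AnnotationDB,
    AnnotationRecord,
    HitRecord,
    HitTable,
    load_ontology,
)


@pytest.fixture
def chain():
    """r <- a <- b: the minimal chain used by most worked examples."""
    return load_ontology([("b", "a", "is_a"), ("a", "r", "is_a")])


@pytest.fixture
def diamond():
    """c has two parents a and b, both children of root r."""
    return load_ontology(
        [
            ("a", "r", "is_a"),
            ("b", "r", "is_a"),
            ("c", "a", "is_a"),
            ("c", "b", "is_a"),
        ]
    )


@pytest.fixture
def forked():
    """Two chains of depth 3 under the root: r <- a <- b <- c and r <- d <- e <- f."""
    return load_ontology(
        [
            ("a", "r", "is_a"),
            ("b", "a", "is_a"),
            ("c", "b", "is_a"),
            ("d", "r", "is_a"),
            ("e", "d", "is_a"),
            ("f", "e", "is_a"),
        ]
    )


def random_dag_edges(rng: np.random.Generator, n_nodes: int):
    """Random single-rooted DAG: node i > 0 points at 1-2 lower-index nodes."""
    edges = []
    for i in range(1, n_nodes):
        parents = {int(rng.integers(i))}
        if i > 1 and rng.random() < 0.3:
            parents.add(int(rng.integers(i)))
        for p in parents:
            edges.append((f"n{i}", f"n{p}", "is_a"))
    return edges


def make_db(*annotations):
    """make_db(("prot", ["t1", "t2"], "IDA"), ...) -> AnnotationDB."""
    records = []
    for protein, terms, *rest in annotations:
        evidence = rest[0] if rest else "IDA"
        for t in terms:
            records.append(AnnotationRecord(protein, t, evidence))
    return AnnotationDB(records=records)


def make_hits(query, *hits):
    """make_hits("q", ("subject", evalue[, ppos[, pident]]), ...) -> HitTable."""
    records = []
    for subject, evalue, *rest in hits:
        ppos = rest[0] if rest else 90.0
        pident = rest[1] if len(rest) > 1 else ppos
        records.append(
            HitRecord(
                query=query,
                subject=subject,
                percent_identity=pident,
                percent_positives=ppos,
                align_length=100,
                evalue=evalue,
                bitscore=50.0,
            )
        )
    return HitTable(query=query, hits=records)
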