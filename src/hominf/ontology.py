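"""Rooted GO-style ontology DAG and the score-propagation algebra.

The ontology is a directed acyclic graph whose edges point from a child
term to its parent(s), converging on a single root per namespace (e.g.
"molecular_function" for MFO). Annotating a protein with a term implies
all ancestral terms up to the root (the true-path rule), so every
predictor and every assessment measure works on *propagated* term sets.
Two propagation flavors are provided:

* max propagation — each parent receives the maximum score of its
  scored descendants (used when scores are reliabilities);
* cumulative propagation — each term receives its own raw count plus
  the counts of all distinct descendants, then the whole set is
  normalized by the maximum (attained at the root).

Relation labels ("is_a", "part_of") are carried on edges but treated
identically during propagation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Sequence, Set, Tuple

import networkx as nx

__all__ = [
    "OntologyError",
    "CycleError",
    "MultipleRootsError",
    "DanglingTermError",
    "UnknownTermError",
    "OntologyGraph",
    "load_ontology",
    "ancestor_table",
    "propagate_max",
    "propagate_cumulative",
    "leaf_terms",
    "branch_of",
    "branch_overlap",
    "deepest_common_term",
]

TermId = str
EdgeRecord = Tuple[str, str, str]  # (child, parent, relation)


class OntologyError(ValueError):
    """Base class for ontology validation failures."""


class CycleError(OntologyError):
    """The child->parent edge set contains a directed cycle."""


class MultipleRootsError(OntologyError):
    """More than one term has no parent (or the graph is disconnected)."""


class DanglingTermError(OntologyError):
    """An edge references a term outside the declared term set."""


class UnknownTermError(OntologyError, KeyError):
    """A term id is not part of the ontology."""


@dataclass
class OntologyGraph:
    """A validated, single-rooted DAG of terms.

    Attributes
    ----------
    graph:
        networkx DiGraph with edges child -> parent, each carrying a
        ``relation`` attribute.
    root:
        The unique term with no outgoing (child -> parent) edge.
    namespace:
        Free-form namespace label (e.g. ``"MFO"``).
    """

    graph: nx.DiGraph
    root: TermId
    namespace: str = "GO"
    _ancestors: Dict[TermId, FrozenSet[TermId]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _depth: Dict[TermId, int] = field(default_factory=dict, repr=False, compare=False)

    @property
    def terms(self) -> Set[TermId]:
        return set(self.graph.nodes)

    def __contains__(self, term: TermId) -> bool:
        return term in self.graph

    def _require(self, term: TermId) -> None:
        if term not in self.graph:
            raise UnknownTermError(f"unknown term: {term!r}")

    def _build_tables(self) -> None:
        # reverse topological order: root first, children after parents
        order = list(reversed(list(nx.topological_sort(self.graph))))
        anc: Dict[TermId, FrozenSet[TermId]] = {}
        depth: Dict[TermId, int] = {}
        for node in order:
            parents = list(self.graph.successors(node))
            if not parents:
                anc[node] = frozenset()
                depth[node] = 0
            else:
                acc: Set[TermId] = set(parents)
                for p in parents:
                    acc |= anc[p]
                anc[node] = frozenset(acc)
                depth[node] = 1 + max(depth[p] for p in parents)
        self._ancestors = anc
        self._depth = depth

    def ancestors(self, term: TermId) -> FrozenSet[TermId]:
        """All terms on any path from *term* to the root (excluding *term*)."""
        self._require(term)
        if not self._ancestors:
            self._build_tables()
        return self._ancestors[term]

    def depth(self, term: TermId) -> int:
        """Length of the longest path from *term* to the root."""
        self._require(term)
        if not self._depth:
            self._build_tables()
        return self._depth[term]

    def children(self, term: TermId) -> Set[TermId]:
        self._require(term)
        return set(self.graph.predecessors(term))

    def parents(self, term: TermId) -> Set[TermId]:
        self._require(term)
        return set(self.graph.successors(term))

    def propagate_membership(self, terms: Iterable[TermId]) -> Set[TermId]:
        """Terms plus all their ancestors (unscored true-path closure)."""
        out: Set[TermId] = set()
        for t in terms:
            out.add(t)
            out |= self.ancestors(t)
        return out


def load_ontology(
    edge_records: Sequence[EdgeRecord],
    namespace: str = "GO",
    terms: Iterable[TermId] | None = None,
) -> OntologyGraph:
    """Build and validate an :class:`OntologyGraph` from child->parent edges.

    Parameters
    ----------
    edge_records:
        ``(child, parent, relation)`` triples.
    terms:
        Optional explicit term universe; edges referencing ids outside it
        raise :class:`DanglingTermError`. Isolated extra terms are allowed
        only if the graph still has a single root, which for a non-empty
        edge set means they are not (so listing unused terms fails fast).
    """
    if not edge_records:
        raise OntologyError("empty edge list")
    g = nx.DiGraph()
    declared = set(terms) if terms is not None else None
    for child, parent, relation in edge_records:
        if not child or not parent:
            raise OntologyError(f"blank term id in edge ({child!r}, {parent!r})")
        if declared is not None and (child not in declared or parent not in declared):
            raise DanglingTermError(
                f"edge ({child!r}, {parent!r}) references an undeclared term"
            )
        g.add_edge(child, parent, relation=relation)
    if declared is not None:
        g.add_nodes_from(declared)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise CycleError(f"cycle detected: {cyc}")
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) != 1:
        raise MultipleRootsError(
            f"expected exactly one root, found {len(roots)}: {sorted(roots)[:5]}"
        )
    # With a unique sink every maximal child->parent path terminates at the
    # root, so reachability of the root holds by construction.
    return OntologyGraph(graph=g, root=roots[0], namespace=namespace)


def ancestor_table(
    graph: OntologyGraph,
) -> Dict[TermId, Tuple[FrozenSet[TermId], int]]:
    """Per-term ancestor closure and depth (longest path to the root)."""
    return {t: (graph.ancestors(t), graph.depth(t)) for t in graph.terms}


def _check_known(scores: Mapping[TermId, float], graph: OntologyGraph) -> None:
    for t in scores:
        if t not in graph:
            raise UnknownTermError(f"scored term not in ontology: {t!r}")


def propagate_max(
    scores: Mapping[TermId, float], graph: OntologyGraph
) -> Dict[TermId, float]:
    """Max-rule score propagation.

    Every scored term and all of its ancestors appear in the output; each
    term's score is the maximum over the input scores of itself and its
    descendants. Idempotent.
    """
    _check_known(scores, graph)
    out: Dict[TermId, float] = {}
    for term, score in scores.items():
        for u in itertools.chain((term,), graph.ancestors(term)):
            prev = out.get(u)
            if prev is None or score > prev:
                out[u] = score
    return out


def propagate_cumulative(
    counts: Mapping[TermId, float], graph: OntologyGraph
) -> Dict[TermId, float]:
    """Cumulative count propagation, normalized to [0, 1].

    Each term receives its own raw count plus the raw counts of all
    *distinct* descendants (a descendant reachable through several paths
    contributes once), so the root accumulates the grand total. All
    values are then divided by the maximum cumulative value.
    """
    _check_known(counts, graph)
    if any(v < 0 for v in counts.values()):
        raise ValueError("cumulative propagation requires non-negative counts")
    out: Dict[TermId, float] = {}
    for term, count in counts.items():
        for u in itertools.chain((term,), graph.ancestors(term)):
            out[u] = out.get(u, 0.0) + count
    top = max(out.values(), default=0.0)
    if top <= 0:
        raise ValueError("all-zero counts: normalization undefined")
    return {t: v / top for t, v in out.items()}


def leaf_terms(terms: Iterable[TermId], graph: OntologyGraph) -> Set[TermId]:
    """Terms of the set that are not an ancestor of any other member.

    For a propagated set this coincides with "has no child inside the
    set"; the ancestor-based definition also behaves sensibly on
    non-propagated sets.
    """
    term_set = set(terms)
    covered: Set[TermId] = set()
    for t in term_set:
        covered |= graph.ancestors(t)
    return term_set - covered


def branch_of(leaf: TermId, graph: OntologyGraph) -> Set[TermId]:
    """The propagation of a single term: itself plus all ancestors."""
    graph._require(leaf)
    return {leaf} | set(graph.ancestors(leaf))


def branch_overlap(b1: Set[TermId], b2: Set[TermId]) -> float:
    """Shared-term fraction: |b1 & b2| divided by the average branch size."""
    if not b1 or not b2:
        raise ValueError("branch overlap undefined for empty branches")
    return len(b1 & b2) / ((len(b1) + len(b2)) / 2.0)


def deepest_common_term(
    b1: Set[TermId], b2: Set[TermId], graph: OntologyGraph
) -> TermId:
    """Lowest common term of two branches.

    The shared term with the longest path to the root; ties are broken
    lexicographically on the term id for reproducibility.
    """
    common = b1 & b2
    if not common:
        raise ValueError("branches share no term (root missing?)")
    return min(common, key=lambda t: (-graph.depth(t), t))
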