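"""Read an OBO ontology into a validated directed acyclic graph.

The Gene Ontology is three DAGs (biological process, molecular function,
cellular component) whose edges point from a child term to its parents and
carry a relation type (``is_a``, ``part_of``, or anything else declared via
``relationship:`` lines).  This module parses an OBO 1.2/1.4 flat file with
:mod:`obonet`, applies the validation rules the rest of the package relies on
(acyclicity, intra-namespace edges, single root per namespace, alt_id
resolution, obsolete-term exclusion) and exposes the structural queries the
table builder needs: ancestor closures, descendant closures and a
deterministic topological order.
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass, field

import networkx as nx
import obonet

from .errors import OntologyError, UnknownTermError

logger = logging.getLogger(__name__)

IS_A = "is_a"
PART_OF = "part_of"

#: OBO namespace names mapped to the short codes used throughout the package.
NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

_TERM_RE = re.compile(r"^GO:\d{7}$")


def normalize_term_id(term: str) -> str:
    """Upper-case the ``GO:`` prefix and validate the 7-digit form."""
    term = term.strip()
    if term[:3].lower() == "go:":
        term = "GO:" + term[3:]
    if not _TERM_RE.match(term):
        raise OntologyError(f"malformed term ID {term!r} (expected GO: plus 7 digits)")
    return term


def normalize_namespace(ns: str) -> str:
    """Map an OBO namespace name or short code to BP/MF/CC."""
    if ns in NAMESPACE_CODES:
        return NAMESPACE_CODES[ns]
    up = ns.upper()
    if up in NAMESPACE_CODES.values():
        return up
    raise OntologyError(f"unknown namespace {ns!r} (expected BP, MF or CC)")


@dataclass(frozen=True)
class Term:
    id: str
    name: str
    namespace: str  # short code BP|MF|CC


@dataclass
class ParseReport:
    """Counts logged after parsing an OBO stream."""

    n_terms: int = 0
    n_edges: int = 0
    n_obsolete: int = 0
    n_dropped_cross_namespace: int = 0
    n_dropped_other_namespace: int = 0  # removed by namespace_filter

    def log(self) -> None:
        logger.info(
            "parsed OBO: %d terms, %d edges, %d obsolete, "
            "%d cross-namespace edges dropped, %d terms outside filter",
            self.n_terms, self.n_edges, self.n_obsolete,
            self.n_dropped_cross_namespace, self.n_dropped_other_namespace,
        )


@dataclass
class OntologyDag:
    """A validated, single-or-multi-namespace GO graph.

    ``graph`` stores one edge per (child, parent, relation) triple, with the
    edge direction child -> parent, so ancestor queries walk *forward* along
    graph edges.
    """

    terms: dict[str, Term]
    graph: nx.MultiDiGraph = field(repr=False)
    roots: dict[str, str]          # namespace code -> root term
    alt_ids: dict[str, str]        # alternative -> primary term ID
    obsolete: set[str]
    report: ParseReport = field(default_factory=ParseReport, repr=False)

    # -- basic access ------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def namespaces(self) -> tuple[str, ...]:
        return tuple(sorted(self.roots))

    def root(self, namespace: str | None = None) -> str:
        """The root term of ``namespace`` (optional iff only one is present)."""
        if namespace is None:
            if len(self.roots) != 1:
                raise OntologyError(
                    f"ontology holds namespaces {self.namespaces}; specify one"
                )
            return next(iter(self.roots.values()))
        return self.roots[normalize_namespace(namespace)]

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary ID; error on unknown terms."""
        term = normalize_term_id(term)
        term = self.alt_ids.get(term, term)
        if term not in self.terms:
            raise UnknownTermError(term)
        return term

    def parents(self, term: str) -> tuple[tuple[str, str], ...]:
        """(parent, relation) pairs for the direct parents of ``term``."""
        self._check(term)
        return tuple(sorted(
            (p, rel) for _, p, rel in self.graph.out_edges(term, keys=True)
        ))

    def children(self, term: str) -> tuple[tuple[str, str], ...]:
        """(child, relation) pairs for the direct children of ``term``."""
        self._check(term)
        return tuple(sorted(
            (c, rel) for c, _, rel in self.graph.in_edges(term, keys=True)
        ))

    def edges(self) -> list[tuple[str, str, str]]:
        """All (child, parent, relation) triples, sorted."""
        return sorted(self.graph.edges(keys=True))

    # -- structural queries ------------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive transitive closure over stored edges (includes ``term``)."""
        self._check(term)
        return frozenset(nx.descendants(self.graph, term)) | {term}

    def descendants(self, term: str) -> frozenset[str]:
        """Reflexive transitive closure in the child direction."""
        self._check(term)
        return frozenset(nx.ancestors(self.graph, term)) | {term}

    def topological_order(self) -> list[str]:
        """Every term after all of its parents; ties broken lexicographically."""
        down = nx.DiGraph()
        down.add_nodes_from(self.terms)
        down.add_edges_from((p, c) for c, p, _ in self.graph.edges(keys=True))
        return list(nx.lexicographical_topological_sort(down))

    def _check(self, term: str) -> None:
        if term not in self.terms:
            raise UnknownTermError(term)


def ancestors(dag: OntologyDag, term: str) -> frozenset[str]:
    return dag.ancestors(term)


def descendants(dag: OntologyDag, term: str) -> frozenset[str]:
    return dag.descendants(term)


def topological_order(dag: OntologyDag) -> list[str]:
    return dag.topological_order()


# ---------------------------------------------------------------------------
# parsing

def parse_obo(source, namespace_filter: str | None = None) -> OntologyDag:
    """Parse an OBO 1.2/1.4 stream, path or text into an :class:`OntologyDag`.

    Obsolete stanzas are recorded but excluded from the graph; ``alt_id``
    lines populate the alt_id map; relationship types other than is_a/part_of
    are retained with their own relation label; edges joining terms of
    different namespaces are dropped and counted in the parse report.

    Raises :class:`OntologyError` on a cycle (naming one), on a parent term
    that is referenced but never defined, or on a namespace with more than one
    root term.
    """
    if isinstance(source, (str, os.PathLike)) and (
        isinstance(source, os.PathLike) or "\n" not in source
    ):
        handle = open(source, encoding="utf-8")
    elif isinstance(source, str):
        handle = io.StringIO(source)
    else:
        handle = source
    try:
        raw = obonet.read_obo(handle, ignore_obsolete=False)
    finally:
        if handle is not source:
            handle.close()

    default_ns = (raw.graph.get("default-namespace") or [None])[0]
    if namespace_filter is not None:
        namespace_filter = normalize_namespace(namespace_filter)

    report = ParseReport()
    terms: dict[str, Term] = {}
    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}

    for node, data in raw.nodes(data=True):
        term = normalize_term_id(node)
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(term)
            continue
        if "name" not in data and "namespace" not in data:
            raise OntologyError(
                f"term {node!r} referenced as a parent but never defined"
            )
        ns = data.get("namespace", default_ns)
        if ns is None:
            raise OntologyError(f"term {term!r} has no namespace")
        ns = normalize_namespace(ns)
        if namespace_filter is not None and ns != namespace_filter:
            report.n_dropped_other_namespace += 1
            continue
        terms[term] = Term(term, data.get("name", ""), ns)
        for alt in data.get("alt_id", []):
            alt_ids[normalize_term_id(alt)] = term

    report.n_obsolete = len(obsolete)

    graph = nx.MultiDiGraph()
    graph.add_nodes_from(terms)
    for child, parent, rel in raw.edges(keys=True):
        child, parent = normalize_term_id(child), normalize_term_id(parent)
        if child in obsolete or parent in obsolete:
            continue
        if child not in terms or parent not in terms:
            # endpoint removed by the namespace filter
            if namespace_filter is not None:
                continue
            raise OntologyError(
                f"edge {child} -> {parent} references an undefined term"
            )
        if terms[child].namespace != terms[parent].namespace:
            report.n_dropped_cross_namespace += 1
            continue
        graph.add_edge(child, parent, key=rel)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyError(f"ontology graph contains a cycle: {path}")

    roots: dict[str, str] = {}
    for term, info in terms.items():
        if graph.out_degree(term) == 0:
            if info.namespace in roots:
                raise OntologyError(
                    f"namespace {info.namespace} has multiple roots: "
                    f"{roots[info.namespace]} and {term}"
                )
            roots[info.namespace] = term

    report.n_terms = len(terms)
    report.n_edges = graph.number_of_edges()
    report.log()
    dag = OntologyDag(terms=terms, graph=graph, roots=roots,
                      alt_ids=alt_ids, obsolete=obsolete, report=report)
    _validate(dag)
    return dag


def build_dag(
    terms: dict[str, Term],
    edges: list[tuple[str, str, str]],
    alt_ids: dict[str, str] | None = None,
    obsolete: set[str] | None = None,
) -> OntologyDag:
    """Construct a validated DAG directly from term and edge lists."""
    graph = nx.MultiDiGraph()
    graph.add_nodes_from(terms)
    for child, parent, rel in edges:
        if child not in terms or parent not in terms:
            raise OntologyError(f"edge {child} -> {parent} references an undefined term")
        graph.add_edge(child, parent, key=rel)
    if not nx.is_directed_acyclic_graph(graph):
        raise OntologyError("graph contains a cycle")
    roots: dict[str, str] = {}
    for term, info in terms.items():
        if graph.out_degree(term) == 0:
            if info.namespace in roots:
                raise OntologyError(f"namespace {info.namespace} has multiple roots")
            roots[info.namespace] = term
    dag = OntologyDag(terms=terms, graph=graph, roots=roots,
                      alt_ids=dict(alt_ids or {}), obsolete=set(obsolete or ()))
    dag.report.n_terms = len(terms)
    dag.report.n_edges = graph.number_of_edges()
    _validate(dag)
    return dag


def _validate(dag: OntologyDag) -> None:
    for child, parent, _ in dag.graph.edges(keys=True):
        if dag.terms[child].namespace != dag.terms[parent].namespace:
            raise OntologyError(f"edge {child} -> {parent} crosses namespaces")
    for ns in {info.namespace for info in dag.terms.values()}:
        if ns not in dag.roots:
            raise OntologyError(f"namespace {ns} has no root")
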