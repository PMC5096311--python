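"""GAF annotation parsing and per-term annotation counts.

A GAF 2.x file lists gene-product -> GO-term annotations, one tab-separated
row per annotation.  Rows are filtered by the standard rules (NOT qualifiers
dropped, obsolete or unknown terms dropped, optional evidence-code exclusion)
and keyed by the DB object ID (column 2); the symbol (column 3) is kept for
display only.

Term counts follow the true-path rule: the annotation frequency of a term
includes the annotations of its descendants.  Two counting modes exist:

``literal``
    closure_count(t) = direct(t) + sum of direct(d) over strict descendants d.
    A gene annotated to two descendants of t contributes twice.
``distinct``
    closure_count(t) = number of distinct genes annotated to t or any
    descendant of t.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field

from .errors import AnnotationError, OntologyError, UnknownGeneError
from .ontology import OntologyDag, normalize_namespace, normalize_term_id

logger = logging.getLogger(__name__)

#: GAF aspect column (col 9) to namespace code.
ASPECT_TO_NAMESPACE = {"P": "BP", "F": "MF", "C": "CC"}
NAMESPACE_TO_ASPECT = {v: k for k, v in ASPECT_TO_NAMESPACE.items()}

COUNTING_MODES = ("literal", "distinct")


@dataclass
class GafReport:
    n_rows: int = 0
    n_retained: int = 0
    n_malformed: int = 0
    n_not_qualifier: int = 0
    n_evidence_excluded: int = 0
    n_unknown_term: int = 0
    n_obsolete_term: int = 0
    n_other_namespace: int = 0

    def log(self) -> None:
        logger.info(
            "parsed GAF: %d rows, %d retained (%d malformed, %d NOT, "
            "%d evidence-excluded, %d unknown term, %d obsolete, "
            "%d other namespace)",
            self.n_rows, self.n_retained, self.n_malformed,
            self.n_not_qualifier, self.n_evidence_excluded,
            self.n_unknown_term, self.n_obsolete_term, self.n_other_namespace,
        )


@dataclass
class AnnotationSet:
    """Gene -> direct (term, evidence) annotations within one namespace."""

    direct: dict[str, set[tuple[str, str]]]
    namespace: str
    symbols: dict[str, str] = field(default_factory=dict)
    report: GafReport = field(default_factory=GafReport, repr=False)

    @property
    def genes(self) -> list[str]:
        return sorted(self.direct)

    def __len__(self) -> int:
        return len(self.direct)

    def __contains__(self, gene: str) -> bool:
        return gene in self.direct

    def direct_terms(self, gene: str) -> frozenset[str]:
        """The gene's direct annotation term set (evidence codes stripped)."""
        if gene not in self.direct:
            raise UnknownGeneError(gene, self.namespace)
        return frozenset(t for t, _ in self.direct[gene])


@dataclass
class TermCounts:
    """Direct and closure annotation counts per term."""

    direct_count: dict[str, int]
    closure_count: dict[str, int]
    mode: str
    n_genes: int


def parse_gaf(
    source,
    dag: OntologyDag,
    namespace: str | None = None,
    evidence_exclude: frozenset[str] | set[str] = frozenset(),
) -> AnnotationSet:
    """Parse a GAF 2.x stream, path or text into an :class:`AnnotationSet`.

    ``namespace`` selects the single ontology to keep (mandatory when the dag
    holds more than one).  Rows are dropped, with counts in the report, when
    the qualifier contains NOT, the evidence code is excluded, the term is
    obsolete or absent from the dag, or the row has fewer than 15 fields.
    Raises :class:`AnnotationError` when no row is retained.
    """
    if namespace is None:
        if len(dag.roots) != 1:
            raise OntologyError("dag holds several namespaces; specify one")
        namespace = next(iter(dag.roots))
    namespace = normalize_namespace(namespace)

    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and "\t" not in source
    ):
        handle = open(source, encoding="utf-8")
    elif isinstance(source, str):
        handle = io.StringIO(source)
    else:
        handle = source

    evidence_exclude = frozenset(evidence_exclude)
    report = GafReport()
    direct: dict[str, set[tuple[str, str]]] = {}
    symbols: dict[str, str] = {}
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            report.n_rows += 1
            fields = line.split("\t")
            if len(fields) < 15:
                report.n_malformed += 1
                continue
            gene, symbol = fields[1], fields[2]
            qualifier, term, evidence, aspect = (
                fields[3], fields[4], fields[6], fields[8]
            )
            if not gene:
                report.n_malformed += 1
                continue
            if "NOT" in qualifier.split("|"):
                report.n_not_qualifier += 1
                continue
            if evidence in evidence_exclude:
                report.n_evidence_excluded += 1
                continue
            if aspect and ASPECT_TO_NAMESPACE.get(aspect) != namespace:
                report.n_other_namespace += 1
                continue
            try:
                term = normalize_term_id(term)
            except OntologyError:
                report.n_malformed += 1
                continue
            if term in dag.obsolete:
                report.n_obsolete_term += 1
                continue
            term = dag.alt_ids.get(term, term)
            if term not in dag.terms:
                report.n_unknown_term += 1
                continue
            if dag.terms[term].namespace != namespace:
                report.n_other_namespace += 1
                continue
            direct.setdefault(gene, set()).add((term, evidence))
            if symbol:
                symbols[gene] = symbol
            report.n_retained += 1
    finally:
        if handle is not source:
            handle.close()

    if report.n_retained == 0:
        raise AnnotationError(
            f"no annotation rows retained for namespace {namespace} "
            f"({report.n_rows} rows seen)"
        )
    report.log()
    return AnnotationSet(direct=direct, namespace=namespace,
                         symbols=symbols, report=report)


def term_counts(
    annset: AnnotationSet, dag: OntologyDag, mode: str = "literal"
) -> TermCounts:
    """Direct and descendant-closure annotation counts for every term.

    ``literal`` sums the direct counts of a term and all its strict
    descendants (a multiply-annotated gene contributes once per annotated
    descendant); ``distinct`` counts distinct genes annotated anywhere in the
    term's descendant closure.
    """
    if mode not in COUNTING_MODES:
        raise ValueError(f"unknown counting mode {mode!r}; expected {COUNTING_MODES}")
    if annset.namespace not in dag.roots:
        raise OntologyError(
            f"annotation namespace {annset.namespace} absent from ontology"
        )

    direct_count: dict[str, int] = {}
    direct_genes: dict[str, set[str]] = {}
    for gene, pairs in annset.direct.items():
        for term in {t for t, _ in pairs}:
            direct_genes.setdefault(term, set()).add(gene)
    for term in dag.terms:
        direct_count[term] = len(direct_genes.get(term, ()))

    closure_count: dict[str, int] = {}
    for term in dag.terms:
        desc = dag.descendants(term)  # reflexive
        if mode == "literal":
            closure_count[term] = sum(direct_count[d] for d in desc)
        else:
            genes: set[str] = set()
            for d in desc:
                genes |= direct_genes.get(d, set())
            closure_count[term] = len(genes)

    return TermCounts(direct_count=direct_count, closure_count=closure_count,
                      mode=mode, n_genes=len(annset.direct))
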