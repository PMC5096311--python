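"""Synthetic ontologies and annotation corpora, plus the worked-example DAG.

The fixture DAG is the seven-term cellular-component fragment around
*intracellular membrane-bounded organelle* (GO:0043231) used throughout the
package's worked examples: six is-a edges and two part-of edges rooted at
GO:0005575.

The random generators produce small but structurally valid OBO/GAF inputs:
term i draws its parents from terms created before it (guaranteeing a single
root and acyclicity), and each gene draws a Poisson number of distinct direct
annotation terms.  Identical specs (including the seed) produce byte-identical
OBO and GAF output, so the generators double as reproducible test fixtures
that exercise the real parsers end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import NAMESPACE_TO_ASPECT, AnnotationSet, GafReport
from .errors import GosimError
from .ontology import IS_A, NAMESPACE_CODES, PART_OF, OntologyDag, Term, build_dag

_CODE_TO_OBO_NS = {v: k for k, v in NAMESPACE_CODES.items()}

#: (child, parent, relation) edges of the worked-example DAG.
FIG2_EDGES: tuple[tuple[str, str, str], ...] = (
    ("GO:0043231", "GO:0043229", IS_A),
    ("GO:0043231", "GO:0043227", IS_A),
    ("GO:0043229", "GO:0043226", IS_A),
    ("GO:0043229", "GO:0005622", PART_OF),
    ("GO:0043227", "GO:0043226", IS_A),
    ("GO:0043226", "GO:0005575", IS_A),
    ("GO:0005622", "GO:0005623", PART_OF),
    ("GO:0005623", "GO:0005575", IS_A),
)

_FIG2_NAMES = {
    "GO:0005575": "cellular_component",
    "GO:0005623": "cell",
    "GO:0005622": "intracellular",
    "GO:0043226": "organelle",
    "GO:0043227": "membrane-bounded organelle",
    "GO:0043229": "intracellular organelle",
    "GO:0043231": "intracellular membrane-bounded organelle",
}


def fig2_dag() -> OntologyDag:
    """The seven-term worked-example DAG (namespace CC, root GO:0005575)."""
    terms = {t: Term(t, name, "CC") for t, name in _FIG2_NAMES.items()}
    return build_dag(terms, list(FIG2_EDGES))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a random ontology + annotation corpus.

    Defaults match the scale used by the package's oracle-equivalence checks:
    small DAGs with modest multiple inheritance and a mixed is-a/part-of edge
    population, annotated by a few dozen genes.
    """

    n_terms: int = 50
    max_parents: int = 3
    part_of_fraction: float = 0.3
    n_genes: int = 40
    mean_direct_terms: float = 3.0
    seed: int = 0
    namespace: str = "CC"

    def __post_init__(self):
        if self.n_terms < 1:
            raise GosimError("n_terms must be >= 1")
        if self.max_parents < 1:
            raise GosimError("max_parents must be >= 1")
        if not 0.0 <= self.part_of_fraction <= 1.0:
            raise GosimError("part_of_fraction must lie in [0, 1]")
        if self.mean_direct_terms <= 0:
            raise GosimError("mean_direct_terms must be positive")


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def random_dag(spec: SyntheticSpec) -> OntologyDag:
    """A single-root random DAG; term i's parents come from terms < i."""
    rng = np.random.default_rng(spec.seed)
    terms = {
        _term_id(i): Term(_term_id(i), f"synthetic term {i}", spec.namespace)
        for i in range(1, spec.n_terms + 1)
    }
    edges: list[tuple[str, str, str]] = []
    for i in range(2, spec.n_terms + 1):
        k = min(int(rng.integers(1, spec.max_parents + 1)), i - 1)
        parents = rng.choice(i - 1, size=k, replace=False) + 1
        for p in sorted(int(x) for x in parents):
            rel = PART_OF if rng.random() < spec.part_of_fraction else IS_A
            edges.append((_term_id(i), _term_id(p), rel))
    return build_dag(terms, edges)


def random_annotations(spec: SyntheticSpec, dag: OntologyDag) -> AnnotationSet:
    """Genes annotated to Poisson(mean_direct_terms) ∨ 1 distinct terms."""
    if spec.n_genes < 1:
        raise GosimError("n_genes must be >= 1")
    if len(dag) == 0:
        raise GosimError("cannot annotate an empty ontology")
    # independent stream from the DAG topology so the corpus can be redrawn
    rng = np.random.default_rng(spec.seed + 1_000_003)
    term_list = sorted(dag.terms)
    direct: dict[str, set[tuple[str, str]]] = {}
    symbols: dict[str, str] = {}
    for g in range(1, spec.n_genes + 1):
        gene = f"SYNGENE{g:04d}"
        m = min(max(1, int(rng.poisson(spec.mean_direct_terms))), len(term_list))
        chosen = rng.choice(len(term_list), size=m, replace=False)
        direct[gene] = {(term_list[int(i)], "IEA") for i in chosen}
        symbols[gene] = f"syn{g}"
    report = GafReport(n_rows=sum(len(v) for v in direct.values()),
                       n_retained=sum(len(v) for v in direct.values()))
    ns = dag.terms[term_list[0]].namespace
    return AnnotationSet(direct=direct, namespace=ns, symbols=symbols,
                         report=report)


# ---------------------------------------------------------------------------
# emitters (round-trip through the real parsers)

def emit_obo(dag: OntologyDag) -> str:
    """Serialize a DAG as OBO 1.2 text; parsing it back reproduces the DAG."""
    alt_by_primary: dict[str, list[str]] = {}
    for alt, primary in dag.alt_ids.items():
        alt_by_primary.setdefault(primary, []).append(alt)

    lines = ["format-version: 1.2", "ontology: gosimtab-synthetic", ""]
    for term in sorted(dag.terms):
        info = dag.terms[term]
        lines += ["[Term]", f"id: {term}", f"name: {info.name}",
                  f"namespace: {_CODE_TO_OBO_NS[info.namespace]}"]
        lines += [f"alt_id: {alt}" for alt in sorted(alt_by_primary.get(term, []))]
        for parent, rel in dag.parents(term):
            if rel == IS_A:
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    for term in sorted(dag.obsolete):
        lines += ["[Term]", f"id: {term}", f"name: obsolete term",
                  "is_obsolete: true", ""]
    return "\n".join(lines)


def emit_gaf(annset: AnnotationSet) -> str:
    """Serialize an AnnotationSet as GAF 2.1 text (round-trippable)."""
    aspect = NAMESPACE_TO_ASPECT[annset.namespace]
    lines = ["!gaf-version: 2.1"]
    for gene in annset.genes:
        symbol = annset.symbols.get(gene, gene)
        for term, evidence in sorted(annset.direct[gene]):
            lines.append("\t".join([
                "SYNTH", gene, symbol, "", term, "SYNTH:0000001", evidence,
                "", aspect, symbol, "", "protein", "taxon:32644",
                "20150101", "SYNTH", "", "",
            ]))
    return "\n".join(lines) + "\n"
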