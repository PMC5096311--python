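"""Naive repeated-traversal reference implementations.

Every function here deliberately re-walks the raw ontology graph and
recounts the raw annotations on every call, with no precomputed state and no
memoization: S-values unwind the full recursive definition, depths enumerate
paths, and information content re-derives the annotation closure from
scratch.  These are the independent oracles the fast table-backed path is
checked against — the two routes must agree to within 1e-12.
"""

from __future__ import annotations

import math

from .annotations import AnnotationSet
from .errors import MissingICError, UnknownGeneError
from .ontology import OntologyDag
from .pairwise import MeasureConfig, SimilarityResult
from .tables import SemanticFactors


# -- raw-graph primitives ---------------------------------------------------

def naive_ancestors(dag: OntologyDag, term: str,
                    factors: SemanticFactors | None = None) -> frozenset[str]:
    """Reflexive ancestor set by depth-first traversal; optionally restricted
    to edges whose relation has a semantic factor."""
    seen: set[str] = set()
    stack = [term]
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        for parent, rel in dag.parents(t):
            if factors is None or rel in factors:
                stack.append(parent)
    return frozenset(seen)


def naive_descendants(dag: OntologyDag, term: str) -> frozenset[str]:
    seen: set[str] = set()
    stack = [term]
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        stack.extend(c for c, _ in dag.children(t))
    return frozenset(seen)


def naive_ic(dag: OntologyDag, annset: AnnotationSet, term: str,
             mode: str = "literal") -> float:
    """Information content by recounting the annotation closure from scratch."""

    # one fresh pass over the raw annotation rows per call
    direct: dict[str, set[str]] = {}
    for g, pairs in annset.direct.items():
        for t, _ in pairs:
            direct.setdefault(t, set()).add(g)

    def closure(t: str) -> int:
        if mode == "literal":
            return sum(len(direct.get(d, ())) for d in naive_descendants(dag, t))
        genes: set[str] = set()
        for d in naive_descendants(dag, t):
            genes |= direct.get(d, set())
        return len(genes)

    c = closure(term)
    if c == 0:
        raise MissingICError(term)
    total = closure(dag.root())
    p = c / total
    return 0.0 if p == 1.0 else -math.log(p)


def naive_depth(dag: OntologyDag, term: str) -> int:
    """Longest root path by exhaustive recursion over parents."""
    parents = dag.parents(term)
    if not parents:
        return 0
    return 1 + max(naive_depth(dag, p) for p, _ in parents)


def naive_svalue(dag: OntologyDag, a: str, t: str,
                 factors: SemanticFactors | None = None) -> float:
    """S_a(t) by direct recursive evaluation of the defining recurrence.

    No memoization: every path from ``t`` down to ``a`` is unwound in full.
    """
    factors = factors or SemanticFactors()
    sub = naive_ancestors(dag, a, factors)

    def s(t: str) -> float:
        if t == a:
            return 1.0
        best = 0.0
        for child, rel in dag.children(t):
            if rel in factors and child in sub:
                best = max(best, factors[rel] * s(child))
        return best

    return s(t)


def naive_sv(dag: OntologyDag, a: str,
             factors: SemanticFactors | None = None) -> float:
    factors = factors or SemanticFactors()
    return math.fsum(naive_svalue(dag, a, t, factors)
                     for t in sorted(naive_ancestors(dag, a, factors)))


# -- term-term oracle -------------------------------------------------------

def naive_term_sim(
    t1: str, t2: str, dag: OntologyDag, annset: AnnotationSet,
    config: MeasureConfig, factors: SemanticFactors | None = None,
    counting_mode: str = "literal",
) -> float:
    """Term similarity recomputed from the raw graph and raw annotations."""
    factors = factors or SemanticFactors()
    measure = config.measure

    if measure == "wang":
        if t1 == t2:
            return 1.0
        ta = naive_ancestors(dag, t1, factors)
        tb = naive_ancestors(dag, t2, factors)
        num = math.fsum(
            naive_svalue(dag, t1, t, factors) + naive_svalue(dag, t2, t, factors)
            for t in sorted(ta & tb)
        )
        return num / (naive_sv(dag, t1, factors) + naive_sv(dag, t2, factors))

    common = naive_ancestors(dag, t1) & naive_ancestors(dag, t2)

    if measure == "pekar":
        t_a = min(common, key=lambda t: (-naive_depth(dag, t), t))
        da = naive_depth(dag, t_a)
        if config.pekar_variant == "as_printed":
            denom = da + naive_depth(dag, t1) + naive_depth(dag, t2)
        else:
            denom = da + _naive_dist(dag, t1, t_a) + _naive_dist(dag, t2, t_a)
        return da / denom if denom else 0.0

    # IC family: recompute the MICA by scanning the common-ancestor set
    ics = {}
    for t in sorted(common):
        try:
            ics[t] = naive_ic(dag, annset, t, counting_mode)
        except MissingICError:
            pass
    if not ics:
        raise MissingICError(t1)
    mica_ic = max(ics[t] for t in sorted(ics))
    ic1 = naive_ic(dag, annset, t1, counting_mode)
    ic2 = naive_ic(dag, annset, t2, counting_mode)

    if measure == "resnik":
        return mica_ic
    if measure == "lin":
        if t1 == t2:
            return 1.0
        return 2.0 * mica_ic / (ic1 + ic2) if ic1 + ic2 else 0.0
    value = 1.0 - (ic1 + ic2 - 2.0 * mica_ic)
    return max(value, 0.0) if config.jiang_clamp else value


def _naive_dist(dag: OntologyDag, term: str, anc: str) -> int:
    """Longest path from ``anc`` down to ``term`` inside term's ancestor sub-DAG."""
    if term == anc:
        return 0
    best = -1
    for parent, _ in dag.parents(term):
        if anc in naive_ancestors(dag, parent):
            best = max(best, _naive_dist(dag, parent, anc))
    assert best >= 0, "anc must be an ancestor of term"
    return best + 1


# -- gene-gene oracle -------------------------------------------------------

def naive_gene_sim(
    g1: str, g2: str, dag: OntologyDag, annset: AnnotationSet,
    config_or_measure, factors: SemanticFactors | None = None,
    counting_mode: str = "literal",
) -> SimilarityResult:
    """Gene similarity recomputed per query, pairwise or group-wise.

    ``config_or_measure`` is a :class:`MeasureConfig` for the pairwise
    measures or the string ``"simui"`` / ``"simgic"``.
    """
    for g in (g1, g2):
        if g not in annset:
            raise UnknownGeneError(g, annset.namespace)

    if isinstance(config_or_measure, str):
        measure = config_or_measure
        c1 = _naive_closure(dag, annset, g1)
        c2 = _naive_closure(dag, annset, g2)
        if measure == "simui":
            value = len(c1 & c2) / len(c1 | c2)
        else:
            def total(terms):
                return math.fsum(naive_ic(dag, annset, t, counting_mode)
                                 for t in sorted(terms))
            denom = total(c1 | c2)
            value = (1.0 if c1 == c2 else 0.0) if denom == 0.0 \
                else total(c1 & c2) / denom
        return SimilarityResult(g1, g2, measure, "groupwise", value)

    config = config_or_measure
    rows = sorted(annset.direct_terms(g1))
    cols = sorted(annset.direct_terms(g2))
    matrix = [[naive_term_sim(r, c, dag, annset, config, factors, counting_mode)
               for c in cols] for r in rows]
    flat = [v for row in matrix for v in row]
    if config.rule == "max":
        value = max(flat)
    elif config.rule == "avg":
        value = sum(flat) / len(flat)
    else:
        row_max = [max(row) for row in matrix]
        col_max = [max(matrix[i][j] for i in range(len(rows)))
                   for j in range(len(cols))]
        value = (sum(row_max) + sum(col_max)) / (len(rows) + len(cols))
    return SimilarityResult(g1, g2, config.measure, config.rule, value)


def _naive_closure(dag: OntologyDag, annset: AnnotationSet, gene: str) -> frozenset[str]:
    full: set[str] = set()
    for t in annset.direct_terms(gene):
        full |= naive_ancestors(dag, t)
    return frozenset(full)
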