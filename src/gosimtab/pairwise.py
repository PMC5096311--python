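"""Term-term semantic similarity and gene-level combination rules.

Step two of the strategy for the pairwise measures.  Every function here
consumes only the precomputed :class:`~gosimtab.tables.SimilarityTables`; the
ontology graph is never touched, so queries are constant-size lookups plus
arithmetic over stored ancestor maps.

Measures
--------
resnik   IC of the most informative common ancestor (MICA).
lin      2*IC(MICA) / (IC(t1) + IC(t2)), in [0, 1].
jiang    1 - (IC(t1) + IC(t2) - 2*IC(MICA)); may be negative unless clamped.
pekar    depth-based ratio at the deepest common ancestor; two variants, see
         :func:`sim_pekar`.
wang     S-value overlap ratio over the shared ancestors of the two terms.

Gene-level rules over the m x n term-similarity matrix of two genes' direct
annotation sets: ``max`` (global maximum), ``avg`` (grand mean), ``bma``
(best-match average: row maxima and column maxima, averaged over m + n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .annotations import AnnotationSet
from .errors import GosimError, MissingICError, UnknownGeneError
from .tables import ICTable, AncestorTable, SimilarityTables, SValueTable

PAIRWISE_MEASURES = ("resnik", "lin", "jiang", "pekar", "wang")
RULES = ("max", "avg", "bma")
PEKAR_VARIANTS = ("as_printed", "classic")


@dataclass(frozen=True)
class MeasureConfig:
    """A measure, a gene-level rule, and measure-specific variant flags."""

    measure: str = "wang"
    rule: str = "bma"
    jiang_clamp: bool = False
    pekar_variant: str = "as_printed"

    def __post_init__(self):
        if self.measure not in PAIRWISE_MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.pekar_variant not in PEKAR_VARIANTS:
            raise ValueError(f"unknown pekar variant {self.pekar_variant!r}")


class SimilarityResult(NamedTuple):
    entity1: str
    entity2: str
    measure: str
    rule: str
    value: float


@dataclass
class TermSimMatrix:
    """Term-similarity matrix between two genes' annotation term lists."""

    rows: list[str]
    cols: list[str]
    values: np.ndarray


# ---------------------------------------------------------------------------
# term-term measures

def mica(t1: str, t2: str, anc: AncestorTable, ic: ICTable) -> tuple[str, float]:
    """Most informative common ancestor and its IC.

    Scans the intersection of the stored ancestor sets; ties on IC break to
    the lexicographically smallest term ID.  Within one namespace the root is
    always shared, so the intersection is never empty.
    """
    if t1 == t2:
        return t1, ic[t1]
    common = anc[t1] & anc[t2]
    assert common, "terms of one namespace always share the root"
    best, best_ic = None, -math.inf
    for t in sorted(common):
        if t in ic and ic.ic[t] > best_ic:
            best, best_ic = t, ic.ic[t]
    if best is None:
        raise MissingICError(next(iter(common)))
    return best, best_ic


def sim_resnik(t1: str, t2: str, tables: SimilarityTables) -> float:
    """IC of the most informative common ancestor; 0 when only the root is shared."""
    _require_ic(tables.ic, t1, t2)
    return mica(t1, t2, tables.anc, tables.ic)[1]


def sim_lin(t1: str, t2: str, tables: SimilarityTables) -> float:
    """Lin similarity: 2*IC(MICA) / (IC(t1)+IC(t2)); identical terms give 1."""
    _require_ic(tables.ic, t1, t2)
    if t1 == t2:
        return 1.0
    denom = tables.ic[t1] + tables.ic[t2]
    if denom == 0.0:
        return 0.0
    return 2.0 * mica(t1, t2, tables.anc, tables.ic)[1] / denom


def sim_jiang(t1: str, t2: str, tables: SimilarityTables, clamp: bool = False) -> float:
    """Jiang-Conrath: 1 minus the IC distance; negative unless ``clamp``."""
    _require_ic(tables.ic, t1, t2)
    value = 1.0 - (tables.ic[t1] + tables.ic[t2]
                   - 2.0 * mica(t1, t2, tables.anc, tables.ic)[1])
    return max(value, 0.0) if clamp else value


def sim_pekar(
    t1: str, t2: str, tables: SimilarityTables, variant: str = "as_printed"
) -> float:
    """Pekar-Staab depth ratio at the deepest common ancestor t_a.

    ``as_printed`` uses root depths throughout:
    depth(t_a) / (depth(t_a) + depth(t1) + depth(t2)).
    ``classic`` replaces the term depths with the longest-path distances from
    t_a down to each term inside its ancestor sub-DAG:
    depth(t_a) / (depth(t_a) + d(t1, t_a) + d(t2, t_a)).
    A 0/0 ratio (everything at the root) returns 0.
    """
    common = tables.anc[t1] & tables.anc[t2]
    t_a = min(common, key=lambda t: (-tables.depth[t], t))
    da = tables.depth[t_a]
    if variant == "as_printed":
        denom = da + tables.depth[t1] + tables.depth[t2]
    else:
        denom = da + tables.depth.dist[t1][t_a] + tables.depth.dist[t2][t_a]
    return da / denom if denom else 0.0


def sim_wang(t1: str, t2: str, svt: SValueTable) -> float:
    """Wang similarity: shared S-value mass over SV(t1) + SV(t2)."""
    a, b = svt.record(t1), svt.record(t2)
    if t1 == t2:
        return 1.0
    shared = a.keys() & b.keys()
    num = math.fsum(a[t] + b[t] for t in shared)
    return num / (svt.sv[t1] + svt.sv[t2])


def term_similarity(
    t1: str, t2: str, tables: SimilarityTables, config: MeasureConfig
) -> float:
    """Dispatch a term pair to the configured measure."""
    m = config.measure
    if m == "resnik":
        return sim_resnik(t1, t2, tables)
    if m == "lin":
        return sim_lin(t1, t2, tables)
    if m == "jiang":
        return sim_jiang(t1, t2, tables, clamp=config.jiang_clamp)
    if m == "pekar":
        return sim_pekar(t1, t2, tables, variant=config.pekar_variant)
    return sim_wang(t1, t2, tables.svalues)


# ---------------------------------------------------------------------------
# gene-level combination

def build_matrix(
    terms1, terms2, tables: SimilarityTables, config: MeasureConfig
) -> TermSimMatrix:
    rows, cols = sorted(terms1), sorted(terms2)
    values = np.array([
        [term_similarity(r, c, tables, config) for c in cols] for r in rows
    ])
    return TermSimMatrix(rows=rows, cols=cols, values=values)


def combine(matrix: TermSimMatrix, rule: str) -> float:
    """Collapse a term-similarity matrix to one gene-level score."""
    v = matrix.values
    if v.size == 0:
        raise GosimError("cannot combine an empty term-similarity matrix")
    if rule == "max":
        return float(v.max())
    if rule == "avg":
        return float(v.mean())
    if rule == "bma":
        m, n = v.shape
        return float((v.max(axis=1).sum() + v.max(axis=0).sum()) / (m + n))
    raise ValueError(f"unknown rule {rule!r}")


def gene_sim(
    g1: str,
    g2: str,
    annset: AnnotationSet,
    tables: SimilarityTables,
    config: MeasureConfig,
) -> SimilarityResult:
    """Gene functional similarity from the genes' direct annotation sets."""
    for g in (g1, g2):
        if g not in annset:
            raise UnknownGeneError(g, tables.namespace)
    matrix = build_matrix(
        annset.direct_terms(g1), annset.direct_terms(g2), tables, config
    )
    value = combine(matrix, config.rule)
    return SimilarityResult(g1, g2, config.measure, config.rule, value)


def _require_ic(ic: ICTable, *terms: str) -> None:
    for t in terms:
        if t not in ic:
            raise MissingICError(t)
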