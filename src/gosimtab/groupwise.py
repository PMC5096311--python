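"""Group-wise gene functional similarity: simUI and simGIC.

Both measures compare the genes' annotation closures A(g) — direct terms plus
all of their ancestors — as whole sets, reading them straight from the
precomputed gene table.  simUI is the Jaccard ratio of the two closures;
simGIC weights each term by its information content.
"""

from __future__ import annotations

import math

from .errors import MissingICError, UnknownGeneError
from .pairwise import SimilarityResult
from .tables import GeneTermTable, ICTable, SimilarityTables

GROUPWISE_MEASURES = ("simui", "simgic")
GROUPWISE_RULE = "groupwise"


def sim_ui(g1: str, g2: str, gt: GeneTermTable) -> float:
    """Jaccard ratio |A(g1) ∩ A(g2)| / |A(g1) ∪ A(g2)| of annotation closures.

    Strictly positive within one namespace: both closures contain the root.
    """
    a, b = _closures(g1, g2, gt)
    return len(a & b) / len(a | b)


def sim_gic(
    g1: str,
    g2: str,
    gt: GeneTermTable,
    ic: ICTable,
    missing_ic: str = "error",
) -> float:
    """IC-weighted closure overlap: sum IC over A(g1) ∩ A(g2) / sum over the union.

    Closure terms absent from the IC table (zero annotations in the corpus)
    raise :class:`MissingICError` by default; with ``missing_ic="zero"`` they
    contribute IC 0.  When the union carries zero total IC (all terms are the
    root), identical closures score 1 and different closures 0.
    """
    a, b = _closures(g1, g2, gt)

    def total(terms) -> float:
        vals = []
        for t in sorted(terms):
            if t in ic:
                vals.append(ic.ic[t])
            elif missing_ic == "error":
                raise MissingICError(t)
        return math.fsum(vals)

    denom = total(a | b)
    if denom == 0.0:
        return 1.0 if a == b else 0.0
    return total(a & b) / denom


def gene_sim_groupwise(
    g1: str, g2: str, tables: SimilarityTables, measure: str,
    missing_ic: str = "error",
) -> SimilarityResult:
    """Dispatch a gene pair to simUI or simGIC over the table bundle."""
    if measure == "simui":
        value = sim_ui(g1, g2, tables.genes)
    elif measure == "simgic":
        value = sim_gic(g1, g2, tables.genes, tables.ic, missing_ic=missing_ic)
    else:
        raise ValueError(f"unknown group-wise measure {measure!r}")
    return SimilarityResult(g1, g2, measure, GROUPWISE_RULE, value)


def _closures(g1: str, g2: str, gt: GeneTermTable):
    for g in (g1, g2):
        if g not in gt:
            raise UnknownGeneError(g)
    return gt.closure[g1], gt.closure[g2]
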