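"""The fast-vs-naive equivalence experiment.

Draws seeded random ontologies and corpora, answers the same queries through
the table-backed path and through the naive repeated-traversal path, and
reports the largest absolute disagreement.  Because step one stores exact
quantities (not approximations), the two routes must agree to floating-point
noise; the experiment makes that claim measurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .groupwise import GROUPWISE_MEASURES, gene_sim_groupwise
from .naive import naive_gene_sim, naive_term_sim
from .pairwise import (
    PAIRWISE_MEASURES,
    PEKAR_VARIANTS,
    RULES,
    MeasureConfig,
    gene_sim,
    term_similarity,
)
from .synthetic import SyntheticSpec, random_annotations, random_dag
from .tables import build_tables


@dataclass
class EquivalenceReport:
    n_instances: int
    n_comparisons: int
    max_abs_diff: float


def _term_configs() -> list[MeasureConfig]:
    configs = [MeasureConfig(measure=m) for m in PAIRWISE_MEASURES
               if m != "pekar"]
    configs += [MeasureConfig(measure="pekar", pekar_variant=v)
                for v in PEKAR_VARIANTS]
    return configs


def oracle_equivalence(
    n_instances: int = 100,
    seed: int = 0,
    max_terms: int = 50,
    max_parents: int = 3,
    max_genes: int = 40,
    n_term_pairs: int = 3,
    n_gene_pairs: int = 2,
) -> EquivalenceReport:
    """Compare table-backed and naive answers over random instances.

    Each instance draws a DAG of up to ``max_terms`` terms (up to
    ``max_parents`` parents per term) and a corpus of up to ``max_genes``
    genes, builds the tables once, then checks sampled term pairs under every
    pairwise measure (both Pekar variants) and sampled gene pairs under every
    measure x rule combination plus simUI and simGIC.
    """
    rng = np.random.default_rng(seed)
    gene_configs = [MeasureConfig(measure=m, rule=r, pekar_variant=v)
                    for m in PAIRWISE_MEASURES
                    for r in RULES
                    for v in (PEKAR_VARIANTS if m == "pekar" else ("as_printed",))]
    worst = 0.0
    n_comparisons = 0
    for i in range(n_instances):
        spec = SyntheticSpec(
            n_terms=int(rng.integers(5, max_terms + 1)),
            max_parents=max_parents,
            part_of_fraction=float(rng.uniform(0.0, 0.6)),
            n_genes=int(rng.integers(3, max_genes + 1)),
            mean_direct_terms=float(rng.uniform(1.0, 4.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        dag = random_dag(spec)
        annset = random_annotations(spec, dag)
        tables = build_tables(dag, annset)

        terms = sorted(tables.ic.ic)
        for _ in range(n_term_pairs):
            t1 = terms[rng.integers(len(terms))]
            t2 = terms[rng.integers(len(terms))]
            for config in _term_configs():
                fast = term_similarity(t1, t2, tables, config)
                slow = naive_term_sim(t1, t2, dag, annset, config)
                worst = max(worst, abs(fast - slow))
                n_comparisons += 1

        genes = annset.genes
        for _ in range(n_gene_pairs):
            g1 = genes[rng.integers(len(genes))]
            g2 = genes[rng.integers(len(genes))]
            for config in gene_configs:
                fast = gene_sim(g1, g2, annset, tables, config).value
                slow = naive_gene_sim(g1, g2, dag, annset, config).value
                worst = max(worst, abs(fast - slow))
                n_comparisons += 1
            for measure in GROUPWISE_MEASURES:
                fast = gene_sim_groupwise(g1, g2, tables, measure).value
                slow = naive_gene_sim(g1, g2, dag, annset, measure).value
                worst = max(worst, abs(fast - slow))
                n_comparisons += 1

    return EquivalenceReport(n_instances=n_instances,
                             n_comparisons=n_comparisons,
                             max_abs_diff=worst)
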