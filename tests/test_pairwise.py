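"""Term-term measures, combination rules and gene-level pairwise similarity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import array_shapes, arrays

import gosimtab as g
from gosimtab.pairwise import (
    MeasureConfig,
    TermSimMatrix,
    build_matrix,
    combine,
    gene_sim,
    mica,
    sim_jiang,
    sim_lin,
    sim_pekar,
    sim_resnik,
    sim_wang,
    term_similarity,
)

from conftest import make_instance

WANG_EXAMPLE = 1.12 / 4.52  # shared S-value mass over SV(A)+SV(B)


class TestMica:
    def test_self_is_own_mica(self, fig2_tables):
        t = "GO:0043227"
        assert mica(t, t, fig2_tables.anc, fig2_tables.ic) == (
            t, fig2_tables.ic.ic[t])

    def test_root_only_common_ancestor(self, fig2_tables):
        term, ic = mica("GO:0043227", "GO:0005622",
                        fig2_tables.anc, fig2_tables.ic)
        assert term == "GO:0005575" and ic == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        _, dag, annset = make_instance(seed, n_terms=25, n_genes=15)
        tables = g.build_tables(dag, annset)
        terms = sorted(tables.ic.ic)
        for t1 in terms[:8]:
            for t2 in terms[-8:]:
                if t1 == t2:
                    continue
                common = dag.ancestors(t1) & dag.ancestors(t2)
                scored = sorted(
                    ((tables.ic.ic[t], t) for t in common if t in tables.ic),
                    key=lambda x: (-x[0], x[1]))
                best_term, best_ic = mica(t1, t2, tables.anc, tables.ic)
                assert best_ic == scored[0][0]
                assert best_term == scored[0][1]


class TestICMeasures:
    def test_resnik_self_and_root_only(self, fig2_tables):
        t = "GO:0043227"
        assert sim_resnik(t, t, fig2_tables) == fig2_tables.ic.ic[t]
        assert sim_resnik("GO:0043227", "GO:0005622", fig2_tables) == 0.0

    def test_lin_self_is_one_even_at_root(self, fig2_tables):
        assert sim_lin("GO:0005575", "GO:0005575", fig2_tables) == 1.0
        assert sim_lin("GO:0043227", "GO:0043227", fig2_tables) == 1.0
        assert sim_lin("GO:0043227", "GO:0005622", fig2_tables) == 0.0

    def test_jiang_direct_substitution(self, fig2_tables):
        # both terms have IC ln(3); only the root (IC 0) is shared
        ic = fig2_tables.ic.ic["GO:0043227"]
        expected = 1.0 - 2.0 * ic
        assert sim_jiang("GO:0043227", "GO:0005622", fig2_tables) == pytest.approx(
            expected, abs=1e-15)
        assert expected < 0
        assert sim_jiang("GO:0043227", "GO:0005622", fig2_tables, clamp=True) == 0.0
        assert sim_jiang("GO:0043227", "GO:0043227", fig2_tables) == pytest.approx(
            1.0, abs=1e-15)

    def test_missing_ic_raises(self, fig2_tables):
        with pytest.raises(g.MissingICError, match="GO:0043231"):
            sim_resnik("GO:0043231", "GO:0005622", fig2_tables)


class TestPekar:
    def test_as_printed_fixture_values(self, fig2_tables):
        assert sim_pekar("GO:0043227", "GO:0005622", fig2_tables) == 0.0
        assert sim_pekar("GO:0043231", "GO:0005622", fig2_tables) == 0.25

    def test_classic_self_similarity_is_one(self, fig2_tables):
        for t in ("GO:0043231", "GO:0005622", "GO:0043227"):
            assert sim_pekar(t, t, fig2_tables, variant="classic") == 1.0

    def test_root_pair_is_zero(self, fig2_tables):
        for variant in ("as_printed", "classic"):
            assert sim_pekar("GO:0005575", "GO:0005575", fig2_tables,
                             variant=variant) == 0.0


class TestWang:
    def test_worked_example(self, fig2_tables):
        value = sim_wang("GO:0043227", "GO:0005622", fig2_tables.svalues)
        assert value == pytest.approx(WANG_EXAMPLE, abs=1e-12)
        assert round(value, 2) == 0.25

    def test_self_similarity_exactly_one(self, fig2_tables):
        for t in fig2_tables.svalues.svalues:
            assert sim_wang(t, t, fig2_tables.svalues) == 1.0

    def test_missing_record_names_term(self, fig2_tables):
        with pytest.raises(g.UnknownTermError, match="GO:9999999"):
            sim_wang("GO:9999999", "GO:0005622", fig2_tables.svalues)


class TestCombine:
    def test_singleton_matrix_all_rules(self):
        m = TermSimMatrix(["a"], ["b"], np.array([[0.7]]))
        for rule in ("max", "avg", "bma"):
            assert combine(m, rule) == 0.7

    def test_identity_matrix_closed_form(self):
        m = TermSimMatrix(["a", "b"], ["c", "d"], np.eye(2))
        assert combine(m, "max") == 1.0
        assert combine(m, "avg") == 0.5
        assert combine(m, "bma") == 1.0

    def test_empty_matrix_is_error(self):
        m = TermSimMatrix([], [], np.zeros((0, 0)))
        with pytest.raises(g.GosimError):
            combine(m, "max")

    @given(arrays(np.float64, array_shapes(min_dims=2, max_dims=2, max_side=6),
                  elements=st.floats(-1, 1)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rules_match_direct_formulas(self, values):
        m = TermSimMatrix([f"r{i}" for i in range(values.shape[0])],
                          [f"c{j}" for j in range(values.shape[1])], values)
        rows, cols = values.shape
        assert combine(m, "max") == max(map(max, values.tolist()))
        assert combine(m, "avg") == pytest.approx(
            sum(map(sum, values.tolist())) / (rows * cols), abs=1e-12)
        expected_bma = (
            sum(max(row) for row in values.tolist())
            + sum(max(values[i][j] for i in range(rows)) for j in range(cols))
        ) / (rows + cols)
        assert combine(m, "bma") == pytest.approx(expected_bma, abs=1e-12)


class TestGeneSim:
    def test_identical_single_term_genes_score_one(self, fig2, fig2_tables):
        annset = g.AnnotationSet(
            direct={"g1": {("GO:0043227", "IEA")}, "g2": {("GO:0043227", "IEA")}},
            namespace="CC",
        )
        for measure in ("lin", "wang", "jiang"):
            res = gene_sim("g1", "g2", annset, fig2_tables,
                           MeasureConfig(measure=measure))
            assert res.value == pytest.approx(1.0, abs=1e-15)

    def test_worked_example_single_term_genes(self, fig2_annset, fig2_tables):
        for rule in ("max", "avg", "bma"):
            res = gene_sim("gA", "gB", fig2_annset, fig2_tables,
                           MeasureConfig(measure="wang", rule=rule))
            assert res.value == pytest.approx(WANG_EXAMPLE, abs=1e-12)

    def test_unannotated_gene_error_names_gene(self, fig2_annset, fig2_tables):
        with pytest.raises(g.UnknownGeneError, match="nosuch"):
            gene_sim("gA", "nosuch", fig2_annset, fig2_tables, MeasureConfig())


class TestInvariants:
    @pytest.mark.parametrize("seed", range(4))
    def test_symmetry_and_ranges(self, seed):
        _, dag, annset = make_instance(seed, n_terms=30, n_genes=12)
        tables = g.build_tables(dag, annset)
        terms = sorted(tables.ic.ic)
        rng = np.random.default_rng(seed)
        pairs = [(terms[rng.integers(len(terms))], terms[rng.integers(len(terms))])
                 for _ in range(6)]
        for t1, t2 in pairs:
            for measure in ("resnik", "lin", "jiang", "pekar", "wang"):
                for variant in ("as_printed", "classic"):
                    c = MeasureConfig(measure=measure, pekar_variant=variant)
                    a = term_similarity(t1, t2, tables, c)
                    b = term_similarity(t2, t1, tables, c)
                    assert a == b
            assert sim_resnik(t1, t2, tables) >= 0.0
            assert 0.0 <= sim_lin(t1, t2, tables) <= 1.0
            assert 0.0 < sim_wang(t1, t2, tables.svalues) <= 1.0
            assert 0.0 <= sim_pekar(t1, t2, tables) < 1.0
            assert sim_jiang(t1, t2, tables) <= 1.0
        genes = annset.genes
        gpairs = [(genes[rng.integers(len(genes))], genes[rng.integers(len(genes))])
                  for _ in range(4)]
        for g1, g2 in gpairs:
            for rule in ("max", "avg", "bma"):
                c = MeasureConfig(measure="wang", rule=rule)
                assert gene_sim(g1, g2, annset, tables, c).value == pytest.approx(
                    gene_sim(g2, g1, annset, tables, c).value, abs=1e-12)

    def test_queries_survive_deleting_the_graph(self, fig2, fig2_annset):
        """Step two touches only the tables: the dag object can be discarded."""
        tables = g.build_tables(fig2, fig2_annset)
        annset = fig2_annset
        del fig2
        assert sim_wang("GO:0043227", "GO:0005622",
                        tables.svalues) == pytest.approx(WANG_EXAMPLE, abs=1e-12)
        assert sim_resnik("GO:0043227", "GO:0005622", tables) == 0.0
        res = gene_sim("gA", "gB", annset, tables, MeasureConfig(measure="lin"))
        assert res.value == 0.0
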