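import pytest

import gosimtab as g


@pytest.fixture(scope="session")
def fig2():
    """The seven-term worked-example DAG."""
    return g.fig2_dag()


@pytest.fixture(scope="session")
def fig2_annset():
    """Three genes annotated to a leaf-ish term, a mid term, and the root."""
    return g.AnnotationSet(
        direct={
            "gA": {("GO:0043227", "IEA")},
            "gB": {("GO:0005622", "IEA")},
            "gC": {("GO:0005575", "IEA")},
        },
        namespace="CC",
    )


@pytest.fixture(scope="session")
def fig2_tables(fig2, fig2_annset):
    return g.build_tables(fig2, fig2_annset)


def make_instance(seed, n_terms=50, n_genes=40, **kw):
    """A seeded random DAG + corpus + table bundle."""
    spec = g.SyntheticSpec(n_terms=n_terms, n_genes=n_genes, seed=seed, **kw)
    dag = g.random_dag(spec)
    annset = g.random_annotations(spec, dag)
    return spec, dag, annset
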