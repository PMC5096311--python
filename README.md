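# gosimtab

Fast Gene Ontology (GO) semantic similarity and gene functional similarity
from precomputed lookup tables.

Measuring how functionally similar two genes are — for gene clustering,
protein-interaction prediction, function prediction or disease-gene
prioritisation — usually means comparing the GO terms that annotate them.
Every popular measure needs quantities that live in the GO graph (common
ancestors, information content, depths, Wang S-values, annotation closures),
and recomputing them by walking the graph for every query pair is what makes
genome-scale runs slow. `gosimtab` splits the work in two:

1. **build** — one pass over the ontology (OBO) and the annotation corpus
   (GAF) compiles, per namespace, every quantity any supported measure will
   ever ask for, into plain keyed tables that are saved as TSV;
2. **query** — term–term and gene–gene similarity queries are answered from
   those tables alone, in constant-size lookups, with results identical to
   recomputing everything from the graph per query (the test suite checks
   agreement with a naive repeated-traversal oracle to 1e-12).

## Measures

For terms $t_1, t_2$ with most informative common ancestor (MICA, the common
ancestor maximising information content $IC(t) = -\ln p(t)$, where $p(t)$ is
the annotation-closure frequency of $t$ in the corpus):

- **Resnik** $= IC(\mathrm{MICA})$
- **Lin** $= 2\,IC(\mathrm{MICA}) / (IC(t_1) + IC(t_2))$
- **Jiang–Conrath** $= 1 - (IC(t_1) + IC(t_2) - 2\,IC(\mathrm{MICA}))$
- **Pekar–Staab** $= \delta(t_a)/(\delta(t_a) + \delta(t_1) + \delta(t_2))$
  with $\delta$ the longest-path depth and $t_a$ the deepest common ancestor
  (a `classic` variant using distances to $t_a$ is also provided)
- **Wang** $= \sum_{t \in T_A \cap T_B} (S_A(t) + S_B(t)) \,/\, (SV(A) + SV(B))$,
  where $S_A(A) = 1$, $S_A(t) = \max_{t' \in \mathrm{children}(t)} w_e
  S_A(t')$ with semantic contribution factors $w_{is\text{-}a} = 0.8$,
  $w_{part\text{-}of} = 0.6$, and $SV(A) = \sum_{t \in T_A} S_A(t)$

Gene-level scores combine the term matrix of two genes' direct annotation
sets by the **max**, **average**, or **best-match average** (BMA) rule, or
compare whole annotation closures $A(g)$ group-wise:

- **simUI** $= |A(g_1) \cap A(g_2)| / |A(g_1) \cup A(g_2)|$
- **simGIC** $= \sum_{t \in A(g_1) \cap A(g_2)} IC(t) \,/\,
  \sum_{t \in A(g_1) \cup A(g_2)} IC(t)$

## Worked example

The seven-term cellular-component fragment around *intracellular
membrane-bounded organelle* (GO:0043231) ships as a fixture:

```python
>>> import gosimtab as g
>>> dag = g.fig2_dag()
>>> svt = g.build_svalue_table(dag)          # factors is_a=0.8, part_of=0.6
>>> svt.sv["GO:0043227"], svt.sv["GO:0005622"]
(2.4400000000000004, 2.08)
>>> g.sim_wang("GO:0043227", "GO:0005622", svt)
0.24778761061946902
```

GO:0043227 (*membrane-bounded organelle*) contributes S-values
1.0 + 0.8 + 0.64 = 2.44 over its three ancestors, GO:0005622
(*intracellular*) contributes 1.0 + 0.6 + 0.48 = 2.08; their only shared
ancestor is the root, where the two S-values sum to 0.48 + 0.64 = 1.12, so
the Wang similarity is 1.12 / 4.52 ≈ 0.25.

The same query through the command line:

```sh
gosimtab build --obo fig2.obo --gaf fig2.gaf --namespace CC --out tables/
printf 'GO:0043227\tGO:0005622\n' > pairs.tsv
gosimtab termsim --tables tables/ --measure wang --pairs pairs.tsv --out out.tsv
```

`gosimtab simulate` writes seeded synthetic OBO/GAF pairs for testing, and
`gosimtab genesim` scores gene pairs with any measure and rule.

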