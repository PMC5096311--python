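# Methods

## The two-step model

All supported similarity measures are deterministic functions of a small set
of per-term and per-gene quantities: information content, longest-path depth,
Wang S-value maps, reflexive ancestor sets, and gene annotation closures.
`gosimtab` computes these once per (ontology, corpus, namespace) triple —
each in a single pass over a topological order of the DAG — and stores them
in keyed in-memory maps, persisted as sorted TSV. Queries then never touch
the graph: deleting the `OntologyDag` after the build does not affect any
answer, and the test suite enforces this. Because the stored quantities are
exact (not summaries or approximations), the table-backed answers are
bit-for-bit reproductions of what per-query graph traversal would compute;
the equivalence experiment (`gosimtab.validation.oracle_equivalence`)
measures the residual floating-point disagreement, which is bounded by
summation-order effects only (observed ≤ 1e-15, asserted ≤ 1e-12).

## Ontology handling

OBO parsing is delegated to `obonet`; on top of the raw graph we enforce the
structural contract the tables rely on: acyclicity (a cycle is a hard error
naming one offending path), a single root per namespace, intra-namespace
edges only (cross-namespace edges are dropped and counted), alt_id
resolution at parse time so downstream code only ever sees primary IDs, and
exclusion of obsolete terms from the graph while remembering them so that
annotations to them can be reported. Relationship types beyond `is_a` and
`part_of` (e.g. `regulates`) are kept in the graph and participate in
ancestor sets, depths and closures, but are excluded from Wang S-value
propagation — the Wang measure defines semantic contribution factors only
for is-a (0.8) and part-of (0.6), and an edge without a factor cannot
contribute semantics. Both the factor values and the set of propagating
relations are configurable; factors must lie strictly in (0, 1) so that
contributions decay.

## Annotation counts and information content

The probability of a term is its annotation-closure frequency:
`p(t) = closure_count(t) / closure_count(root)`, `IC(t) = -ln p(t)` (natural
log; the base is recorded in the table manifest). Two closure-counting modes
exist:

- **literal** (default): `closure_count(t)` is the direct count of `t` plus
  the *sum* of direct counts over all strict descendants. A gene annotated to
  two descendants of `t` contributes twice. This is the plain reading of the
  frequency formula and is what the package reproduces by default.
- **distinct**: the number of distinct genes annotated to `t` or any
  descendant. This is the variant most IC implementations use in practice;
  it avoids the double-counting of multiply-annotated genes.

Both modes are monotone along edges, and the denominator is the root's own
closure count including the root's direct annotations, which pins
`p(root) = 1` and `IC(root) = 0` exactly. Terms with zero closure count have
no defined probability and are absent from the IC table; IC-based queries
touching them raise a `MissingICError` naming the term rather than returning
a sentinel value. Direct counts are counts of distinct genes, not of GAF
rows. The default evidence filter is empty (IEA annotations kept); any set
of evidence codes can be excluded at parse time.

## Measure-specific choices

- **MICA ties** (equal IC among common ancestors) and **deepest-common-
  ancestor ties** (equal depth) break to the lexicographically smallest term
  ID, making all outputs deterministic. An identical pair is its own MICA.
- **Lin**: self-similarity is defined as 1 even where IC = 0; a zero IC sum
  for distinct terms returns 0 (unreachable within one namespace, guarded
  anyway).
- **Jiang–Conrath** is reported unclamped by default and can be negative;
  `jiang_clamp` floors it at 0.
- **Pekar–Staab** defaults to the `as_printed` form, which uses each term's
  longest-path depth from the root in the denominator — this is the form
  answerable from a depth table alone. The `classic` variant replaces the
  term depths with the longest-path distances from the chosen ancestor down
  to each term inside that term's ancestor sub-DAG; it needs per-term
  ancestor-distance maps, which are built alongside the depth table and
  persisted as `distances.tsv`. Under `classic`, self-similarity of any
  non-root term is 1. The all-root 0/0 case returns 0 in both variants.
- **Wang**: for each term `A`, the ancestor sub-DAG is the set reachable
  through factored edges only; S-values are computed children-before-parents
  in one topological pass and the semantic value `SV(A)` is cached. The
  similarity of a pair iterates the intersection of the two stored maps.
  `sim(t, t)` is exactly 1.
- **Gene-level pairwise similarity** builds its m×n matrix over the genes'
  *direct* annotation term sets. Using closures instead would put the root
  and shared upper ontology into every matrix and systematically inflate
  scores; direct sets are what the combination rules are meant to summarise.
  BMA is `(Σ_i row-max_i + Σ_j col-max_j) / (m + n)`.
- **simUI / simGIC** compare annotation *closures* (direct terms plus all
  ancestors), the graph-based reading of group-wise similarity; a
  direct-only comparison can be had by building the gene table from direct
  sets. simGIC errors on closure terms with no IC by default
  (`missing_ic="zero"` treats them as weightless).

## Persistence

Tables serialize as sorted two- or three-column TSV files plus a `key=value`
manifest recording namespace, IC log base, counting mode, semantic factors
and per-file row counts. Reals are printed with 17 significant digits, which
round-trips IEEE-754 doubles exactly, so a save/load cycle is bit-exact —
verified in the tests. Loading refuses a directory whose manifest disagrees
with the requested factors or counting mode, or whose files are truncated
relative to the manifest. The build is deterministic: identical inputs and
configuration produce byte-identical table directories.

## Synthetic data

The generators exist to exercise the parsers and to drive the equivalence
experiment, not to mimic GO's statistics. `random_dag` orders terms and
samples each term's parents uniformly from its predecessors, which guarantees
a single root and acyclicity by construction; edges are labelled `part_of`
with a configurable probability (default 0.3) and `is_a` otherwise.
`random_annotations` gives each gene `max(1, Poisson(mean_direct_terms))`
distinct uniformly chosen terms (default mean 3). Defaults are 50 terms, at
most 3 parents per term, and 40 genes — small enough that the deliberately
slow traversal oracle stays tractable, large enough to produce multiple
inheritance, shared ancestors and annotation overlap. What these instances
do **not** reproduce: GO's depth distribution, its heavy-tailed term usage,
evidence-code structure, or corpus sizes — so passing tests certify
algorithmic correctness and exactness of the tables, not calibration of any
measure on real GO data.

The seven-term fixture DAG (root GO:0005575, six is-a edges, two part-of
edges around GO:0043231) is hard-coded; with the default factors its S-value
table and the Wang worked-example quantities
(SV = 2.44 and 2.08, shared-ancestor numerator 1.12, similarity
1.12/4.52 ≈ 0.25) are reproduced exactly, which anchors the implementation
to published reference values.

## The naive oracle

`gosimtab.naive` re-derives every quantity from the raw graph and raw
annotation rows on each call: ancestor sets by DFS, depths by exhaustive
recursion over parents, IC from a fresh recount of the corpus, S-values by
unmemoized recursion over the defining recurrence. It shares no state with
the fast path and holds no tables, so agreement between the two routes is an
end-to-end check of the table construction. The equivalence experiment draws
100 seeded instances (sizes sampled up to the caps above) and compares all
five pairwise measures (both Pekar variants), all three combination rules,
and both group-wise measures on sampled term and gene pairs.

## Known limitations

- Similarity is defined within a single namespace; cross-namespace queries
  are errors by design.
- The S-value and ancestor-distance tables are quadratic-ish in the ancestor
  set sizes; for a full GO release the build takes minutes and the TSV
  directory is large. Rebuild-on-change is the intended workflow — there is
  no incremental update.
- The literal counting mode reproduces the double-counting of
  multiply-annotated genes inherent in the closure-sum frequency formula;
  use `distinct` when comparing against IC values from other tools.
- GAF qualifier semantics beyond `NOT` (e.g. `contributes_to`) are ignored;
  GPAD is not parsed.
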