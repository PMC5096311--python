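"""Compile the ontology and annotations into per-method lookup tables.

This is step one of the two-step strategy: every quantity a similarity query
needs — information content, longest-path depth, Wang S-value maps, ancestor
sets, gene annotation closures — is computed once, in a single topological
pass per table, and stored in plain keyed maps.  Step two (the query modules)
consumes these tables only and never touches the ontology graph again.

Tables persist as a directory of TSV files plus a key=value manifest.  Reals
are printed with 17 significant digits, which round-trips IEEE doubles
bit-exactly, so save -> load reproduces every value with no precision loss.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

from .annotations import AnnotationSet, TermCounts, term_counts as _term_counts
from .errors import AnnotationError, MissingICError, TableIOError, UnknownTermError
from .ontology import IS_A, PART_OF, OntologyDag

FORMAT_VERSION = "1"

#: Semantic contribution factors of the Wang measure (is-a 0.8, part-of 0.6).
DEFAULT_FACTORS = {IS_A: 0.8, PART_OF: 0.6}


@dataclass(frozen=True)
class SemanticFactors:
    """Per-relation semantic contribution factors for S-value propagation.

    Only relations with a configured factor propagate S-values; every factor
    must lie strictly between 0 and 1 so that contributions decay along paths.
    """

    w: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FACTORS))

    def __post_init__(self):
        for rel, weight in self.w.items():
            if not 0.0 < weight < 1.0:
                raise ValueError(
                    f"semantic factor for {rel!r} must be in (0,1), got {weight}"
                )

    def __contains__(self, relation: str) -> bool:
        return relation in self.w

    def __getitem__(self, relation: str) -> float:
        return self.w[relation]

    def items(self):
        return sorted(self.w.items())


@dataclass
class ICTable:
    """Information content IC(t) = -ln p(t) from annotation-closure frequency.

    Terms with zero closure count carry no probability and are absent; looking
    one up raises :class:`MissingICError`.
    """

    ic: dict[str, float]
    p: dict[str, float]

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise MissingICError(term) from None


@dataclass
class DepthTable:
    """Longest-path depths, plus per-term ancestor distances.

    ``depth[t]`` is the edge count of the longest path from the namespace root
    down to ``t``.  ``dist[t][a]`` is the longest path from ancestor ``a``
    down to ``t`` inside the ancestor sub-DAG of ``t`` (needed by the classic
    Pekar variant); ``dist[t][t] == 0``.
    """

    depth: dict[str, int]
    dist: dict[str, dict[str, int]]

    def __getitem__(self, term: str) -> int:
        try:
            return self.depth[term]
        except KeyError:
            raise UnknownTermError(term, "depth table") from None


@dataclass
class SValueTable:
    """Per-term Wang S-value maps and their semantic values SV.

    ``svalues[A]`` maps every ancestor ``t`` reachable from ``A`` through
    factored relations (including ``A`` itself) to S_A(t); ``sv[A]`` caches
    the sum of that map.
    """

    svalues: dict[str, dict[str, float]]
    sv: dict[str, float]

    def record(self, term: str) -> dict[str, float]:
        try:
            return self.svalues[term]
        except KeyError:
            raise UnknownTermError(term, "S-value table") from None


@dataclass
class AncestorTable:
    """Reflexive ancestor set per term (the T(t) of the similarity formulas)."""

    anc: dict[str, frozenset[str]]

    def __getitem__(self, term: str) -> frozenset[str]:
        try:
            return self.anc[term]
        except KeyError:
            raise UnknownTermError(term, "ancestor table") from None


@dataclass
class GeneTermTable:
    """Gene -> annotation closure (direct terms plus all their ancestors)."""

    closure: dict[str, frozenset[str]]

    def __contains__(self, gene: str) -> bool:
        return gene in self.closure


@dataclass
class SimilarityTables:
    """The full bundle of lookup tables for one namespace.

    ``genes`` holds annotation closures (group-wise queries); ``direct`` holds
    the genes' direct annotation term sets (pairwise gene queries).
    """

    namespace: str
    factors: SemanticFactors
    counting_mode: str
    ic: ICTable
    depth: DepthTable
    svalues: SValueTable
    anc: AncestorTable
    genes: GeneTermTable
    direct: GeneTermTable
    root: str

    def annotations(self) -> "AnnotationSet":
        """Rebuild a minimal AnnotationSet view from the direct-term table."""
        return AnnotationSet(
            direct={g: {(t, "") for t in ts}
                    for g, ts in self.direct.closure.items()},
            namespace=self.namespace,
        )


# ---------------------------------------------------------------------------
# builders

def build_ic_table(dag: OntologyDag, counts: TermCounts) -> ICTable:
    """p(t) = closure_count(t) / closure_count(root); IC = -ln p.

    The denominator is the root's own closure count, which makes p(root) = 1
    and IC(root) = 0 exactly.  Zero-count terms are omitted.
    """
    root = dag.root()
    total = counts.closure_count.get(root, 0)
    if total == 0:
        raise AnnotationError(
            f"no annotations in namespace {dag.terms[root].namespace}"
        )
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    for term in dag.terms:
        c = counts.closure_count.get(term, 0)
        if c == 0:
            continue
        p[term] = c / total
        ic[term] = -math.log(p[term])
    ic[root] = 0.0  # guard against -0.0 / rounding on the exact ratio 1
    p[root] = 1.0
    return ICTable(ic=ic, p=p)


def build_depth_table(dag: OntologyDag) -> DepthTable:
    """Longest-path depth per term, plus per-term ancestor distance maps.

    Single pass in topological order: depth(root) = 0, else 1 + max over
    parents.  The ancestor distance map of each term is the same recurrence
    run inside the term's own ancestor sub-DAG.
    """
    order = dag.topological_order()
    depth: dict[str, int] = {}
    for term in order:
        parents = dag.parents(term)
        depth[term] = 0 if not parents else 1 + max(depth[p] for p, _ in parents)

    down: dict[str, set[str]] = {t: set() for t in dag.terms}
    for child, parent, _ in dag.graph.edges(keys=True):
        down[parent].add(child)

    dist: dict[str, dict[str, int]] = {}
    for term in dag.terms:
        sub = dag.ancestors(term)
        d = {term: 0}
        # children before parents within the sub-DAG
        for t in reversed([t for t in order if t in sub]):
            if t == term:
                continue
            d[t] = 1 + max(d[c] for c in down[t] if c in d)
        dist[term] = d
    return DepthTable(depth=depth, dist=dist)


def build_svalue_table(dag: OntologyDag, factors: SemanticFactors | None = None) -> SValueTable:
    """S-value map and semantic value SV for every term.

    For a term A, S_A(A) = 1 and each ancestor t takes the maximum of
    w_e * S_A(t') over its children t' inside the ancestor sub-DAG of A,
    where w_e is the factor of the edge t' -> t.  Only relations with a
    configured factor propagate; other edges are invisible to this table,
    including for reachability.
    """
    factors = factors or SemanticFactors()
    order = dag.topological_order()
    pos = {t: i for i, t in enumerate(order)}

    # factored-edge adjacency in both directions
    up: dict[str, list[tuple[str, float]]] = {t: [] for t in dag.terms}
    down: dict[str, list[tuple[str, float]]] = {t: [] for t in dag.terms}
    for child, parent, rel in dag.graph.edges(keys=True):
        if rel in factors:
            up[child].append((parent, factors[rel]))
            down[parent].append((child, factors[rel]))

    svalues: dict[str, dict[str, float]] = {}
    sv: dict[str, float] = {}
    for term in dag.terms:
        # reachable ancestors through factored edges only
        sub = {term}
        stack = [term]
        while stack:
            for parent, _ in up[stack.pop()]:
                if parent not in sub:
                    sub.add(parent)
                    stack.append(parent)
        s = {term: 1.0}
        for t in sorted(sub - {term}, key=pos.get, reverse=True):
            s[t] = max(w * s[c] for c, w in down[t] if c in sub)
        svalues[term] = s
        sv[term] = math.fsum(s.values())
    return SValueTable(svalues=svalues, sv=sv)


def build_ancestor_table(dag: OntologyDag) -> AncestorTable:
    return AncestorTable({t: dag.ancestors(t) for t in dag.terms})


def build_gene_table(annset: AnnotationSet, dag: OntologyDag) -> GeneTermTable:
    """Annotation closure per gene: union of ancestor sets of direct terms."""
    closure: dict[str, frozenset[str]] = {}
    for gene in annset.genes:
        terms = annset.direct_terms(gene)
        if not terms:
            continue
        full: set[str] = set()
        for t in terms:
            full |= dag.ancestors(t)
        closure[gene] = frozenset(full)
    return GeneTermTable(closure=closure)


def build_tables(
    dag: OntologyDag,
    annset: AnnotationSet,
    factors: SemanticFactors | None = None,
    counting_mode: str = "literal",
) -> SimilarityTables:
    """Build every lookup table for one namespace in one call."""
    factors = factors or SemanticFactors()
    counts = _term_counts(annset, dag, mode=counting_mode)
    return SimilarityTables(
        namespace=annset.namespace,
        factors=factors,
        counting_mode=counting_mode,
        ic=build_ic_table(dag, counts),
        depth=build_depth_table(dag),
        svalues=build_svalue_table(dag, factors),
        anc=build_ancestor_table(dag),
        genes=build_gene_table(annset, dag),
        direct=GeneTermTable({g: annset.direct_terms(g) for g in annset.genes}),
        root=dag.root(),
    )


# ---------------------------------------------------------------------------
# persistence

def _fmt(x: float) -> str:
    return format(x, ".17g")


_FILES = ("ic.tsv", "depth.tsv", "distances.tsv", "svalues.tsv",
          "sv.tsv", "ancestors.tsv", "genes.tsv", "genes_direct.tsv")


def save_tables(tables: SimilarityTables, directory) -> dict[str, int]:
    """Serialize all tables to ``directory`` as sorted TSV plus a manifest.

    Returns the manifest row counts.  Output is deterministic: identical
    tables yield byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows: dict[str, int] = {}

    def write(name: str, lines: list[str]) -> None:
        (directory / name).write_text("".join(f"{l}\n" for l in lines))
        rows[name] = len(lines)

    write("ic.tsv", [f"{t}\t{_fmt(tables.ic.p[t])}\t{_fmt(tables.ic.ic[t])}"
                     for t in sorted(tables.ic.ic)])
    write("depth.tsv", [f"{t}\t{tables.depth.depth[t]}"
                        for t in sorted(tables.depth.depth)])
    write("distances.tsv", [f"{t}\t{a}\t{d}"
                            for t in sorted(tables.depth.dist)
                            for a, d in sorted(tables.depth.dist[t].items())])
    write("svalues.tsv", [f"{t}\t{a}\t{_fmt(s)}"
                          for t in sorted(tables.svalues.svalues)
                          for a, s in sorted(tables.svalues.svalues[t].items())])
    write("sv.tsv", [f"{t}\t{_fmt(tables.svalues.sv[t])}"
                     for t in sorted(tables.svalues.sv)])
    write("ancestors.tsv", [f"{t}\t{a}"
                            for t in sorted(tables.anc.anc)
                            for a in sorted(tables.anc.anc[t])])
    write("genes.tsv", [f"{g}\t{t}"
                        for g in sorted(tables.genes.closure)
                        for t in sorted(tables.genes.closure[g])])
    write("genes_direct.tsv", [f"{g}\t{t}"
                               for g in sorted(tables.direct.closure)
                               for t in sorted(tables.direct.closure[g])])

    manifest = [f"format_version={FORMAT_VERSION}",
                f"namespace={tables.namespace}",
                f"root={tables.root}",
                "ic_log_base=e",
                f"counting_mode={tables.counting_mode}"]
    manifest += [f"factor.{rel}={_fmt(w)}" for rel, w in tables.factors.items()]
    manifest += [f"rows.{name}={rows[name]}" for name in _FILES]
    (directory / "manifest.txt").write_text("".join(f"{l}\n" for l in manifest))
    return rows


def manifest_digest(directory) -> str:
    """SHA-256 of the manifest file, for provenance headers in query output."""
    data = (Path(directory) / "manifest.txt").read_bytes()
    return hashlib.sha256(data).hexdigest()[:12]


def load_tables(
    directory,
    expect_factors: SemanticFactors | None = None,
    expect_counting: str | None = None,
) -> SimilarityTables:
    """Load a table directory saved by :func:`save_tables`.

    Refuses to load when the manifest declares different semantic factors or
    counting mode than the caller expects, or when any file's row count
    disagrees with the manifest (truncation guard).
    """
    directory = Path(directory)
    mpath = directory / "manifest.txt"
    if not mpath.exists():
        raise TableIOError(f"no manifest.txt in {directory}")
    meta: dict[str, str] = {}
    for line in mpath.read_text().splitlines():
        key, _, value = line.partition("=")
        meta[key] = value
    if meta.get("format_version") != FORMAT_VERSION:
        raise TableIOError(f"unsupported table format {meta.get('format_version')!r}")

    factors = SemanticFactors({
        key[len("factor."):]: float(v) for key, v in meta.items()
        if key.startswith("factor.")
    })
    if expect_factors is not None and dict(expect_factors.items()) != dict(factors.items()):
        raise TableIOError(
            f"manifest declares factors {dict(factors.items())}, "
            f"caller requested {dict(expect_factors.items())}"
        )
    counting = meta.get("counting_mode", "literal")
    if expect_counting is not None and counting != expect_counting:
        raise TableIOError(
            f"manifest declares counting mode {counting!r}, "
            f"caller requested {expect_counting!r}"
        )

    def read(name: str) -> list[list[str]]:
        path = directory / name
        if not path.exists():
            raise TableIOError(f"missing table file {name}")
        out = [line.split("\t") for line in path.read_text().splitlines()]
        declared = int(meta.get(f"rows.{name}", -1))
        if len(out) != declared:
            raise TableIOError(
                f"{name} holds {len(out)} rows but manifest declares {declared}"
            )
        return out

    ic, p = {}, {}
    for t, pv, icv in read("ic.tsv"):
        p[t], ic[t] = float(pv), float(icv)
    depth = {t: int(d) for t, d in read("depth.tsv")}
    dist: dict[str, dict[str, int]] = {}
    for t, a, d in read("distances.tsv"):
        dist.setdefault(t, {})[a] = int(d)
    svalues: dict[str, dict[str, float]] = {}
    for t, a, s in read("svalues.tsv"):
        svalues.setdefault(t, {})[a] = float(s)
    sv = {t: float(s) for t, s in read("sv.tsv")}
    anc: dict[str, set[str]] = {}
    for t, a in read("ancestors.tsv"):
        anc.setdefault(t, set()).add(a)
    closure: dict[str, set[str]] = {}
    for g, t in read("genes.tsv"):
        closure.setdefault(g, set()).add(t)
    direct: dict[str, set[str]] = {}
    for g, t in read("genes_direct.tsv"):
        direct.setdefault(g, set()).add(t)

    return SimilarityTables(
        namespace=meta["namespace"],
        factors=factors,
        counting_mode=counting,
        ic=ICTable(ic=ic, p=p),
        depth=DepthTable(depth=depth, dist=dist),
        svalues=SValueTable(svalues=svalues, sv=sv),
        anc=AncestorTable({t: frozenset(s) for t, s in anc.items()}),
        genes=GeneTermTable({g: frozenset(s) for g, s in closure.items()}),
        direct=GeneTermTable({g: frozenset(s) for g, s in direct.items()}),
        root=meta["root"],
    )
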