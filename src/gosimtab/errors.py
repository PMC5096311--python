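"""Exception hierarchy shared across the package."""


class GosimError(Exception):
    """Base class for all errors raised by gosimtab."""


class OntologyError(GosimError):
    """Structural problem in an ontology (cycle, undefined parent, bad root)."""


class UnknownTermError(GosimError, KeyError):
    """A term ID is absent from the ontology or from a lookup table."""

    def __init__(self, term: str, where: str = "ontology"):
        super().__init__(f"unknown term {term!r} (not present in {where})")
        self.term = term


class MissingICError(GosimError, KeyError):
    """A term has no information content (zero annotations in the corpus)."""

    def __init__(self, term: str):
        super().__init__(
            f"term {term!r} has no information content: it annotates no gene "
            "in the corpus the tables were built from"
        )
        self.term = term


class UnknownGeneError(GosimError, KeyError):
    """A gene ID is absent from the annotation set or gene table."""

    def __init__(self, gene: str, namespace: str | None = None):
        ns = f" in namespace {namespace}" if namespace else ""
        super().__init__(f"gene {gene!r} has no annotations{ns}")
        self.gene = gene


class AnnotationError(GosimError):
    """Problem with a GAF stream (e.g. no retained rows)."""


class TableIOError(GosimError):
    """Problem saving or loading a table directory (truncation, mismatch)."""
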