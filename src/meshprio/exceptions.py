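"""Exception hierarchy for meshprio.

All package-specific failures derive from :class:`MeshPrioError` so callers
(and the CLI) can catch one base class.
"""


class MeshPrioError(Exception):
    """Base class for all meshprio errors."""


class ParseError(MeshPrioError, ValueError):
    """An input file violates its declared dialect (names file and line)."""


class DataError(MeshPrioError, ValueError):
    """Structurally valid input with inconsistent content (e.g. a gene in two
    ortholog groups)."""


class ValidationError(MeshPrioError, ValueError):
    """Parameters or derived quantities violate a precondition."""


class UnknownTermError(MeshPrioError, KeyError):
    """A MeSH descriptor is absent from the corpus term index."""


class UndefinedSimilarityError(MeshPrioError, ValueError):
    """A similarity measure is undefined for the given counts (zero
    denominator, or PMI with no co-occurrence)."""


class DegenerateDataError(MeshPrioError, ValueError):
    """A statistical comparison has no information (e.g. all paired
    differences are zero)."""
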