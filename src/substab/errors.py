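"""Exception hierarchy shared across the package."""


class SubstabError(Exception):
    """Base class for all package errors."""


class ValidationError(SubstabError, ValueError):
    """An input violates a documented precondition or invariant."""


class AlignmentShapeError(ValidationError):
    """Rows of a multiple sequence alignment differ in length."""


class MissingTaxonError(SubstabError, LookupError):
    """A requested taxon name is not present."""


class NoOverlapError(SubstabError):
    """A sequence pair shares no comparable (non-missing) columns."""


class NoSitesError(SubstabError):
    """Column filtering removed every alignment column."""


class NewickParseError(SubstabError, ValueError):
    """Malformed Newick input."""


class ReplicateCountWarning(UserWarning):
    """Fewer bootstrap replicates than the recommended minimum of 500."""
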