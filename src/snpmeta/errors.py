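"""Exception hierarchy shared across the package."""


class SnpMetaError(Exception):
    """Base class for all errors raised by snpmeta."""


class SchemaError(SnpMetaError):
    """Input file is missing required columns or has an unusable layout."""


class RowError(SnpMetaError):
    """A data row failed validation.

    Attributes
    ----------
    row : int
        Zero-based row index within the data portion of the file.
    field : str
        Name of the offending column.
    """

    def __init__(self, row: int, field: str, message: str):
        self.row = row
        self.field = field
        super().__init__(f"row {row}, column {field!r}: {message}")


class UndefinedInputError(SnpMetaError):
    """A computation was requested on degenerate input (e.g. zero totals)."""


class DegenerateTableError(SnpMetaError):
    """A 2x2 table has an empty margin even after continuity correction."""


class InsufficientStudiesError(SnpMetaError):
    """Fewer studies than the operation's minimum (k >= 2, 3, ...)."""


class ConvergenceError(SnpMetaError):
    """An MCMC run cannot produce the requested diagnostic."""


class PipelineError(SnpMetaError):
    """A pipeline stage failed; partial outputs were written."""
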