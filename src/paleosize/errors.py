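"""Exception hierarchy for paleosize.

All package-specific failures derive from :class:`PaleosizeError` so callers
can catch one base class at pipeline boundaries.
"""


class PaleosizeError(Exception):
    """Base class for all paleosize errors."""


class SchemaError(PaleosizeError):
    """A table is missing a required column or violates its schema."""


class RowValidationError(PaleosizeError):
    """A single data row fails validation.

    Parameters
    ----------
    message : str
        Human-readable description of the failure.
    line : int, optional
        1-based line number in the source file (header is line 1).
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateKeyError(PaleosizeError):
    """Two rows share a key that must be unique, e.g. (species, period)."""


class DegenerateWeightsError(PaleosizeError):
    """All weights are zero (or the weighted total is zero)."""


class InsufficientDataError(PaleosizeError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(PaleosizeError):
    """The statistic is undefined for the input (e.g. both variances zero)."""
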