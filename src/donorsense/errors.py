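"""Exception hierarchy shared across the package."""


class DonorsenseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DonorsenseError):
    """A simulation or run configuration is internally inconsistent."""


class ValidationError(DonorsenseError):
    """Input data violate a documented precondition."""


class SchemaError(DonorsenseError):
    """A CSV file does not match its declared schema.

    Carries the offending row (0-based, excluding the header) and column
    when they are known.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = ""
        if row is not None:
            loc += f" [row {row}]"
        if column is not None:
            loc += f" [column {column!r}]"
        super().__init__(message + loc)
        self.row = row
        self.column = column


class FittingError(DonorsenseError):
    """A model fit failed (non-convergence, separation, singular design)."""
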