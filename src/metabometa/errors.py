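"""Exception types shared across the pipeline stages."""


class MetabometaError(Exception):
    """Base class for all package errors."""


class DomainError(MetabometaError):
    """A scalar input violates its mathematical domain (e.g. glucose <= 0)."""


class DataError(MetabometaError):
    """Input data violate a structural contract (e.g. negative abundance)."""


class SchemaError(MetabometaError):
    """A table is missing required columns or has inconsistent identifiers."""


class ConfigError(MetabometaError):
    """A configuration object is internally inconsistent."""


class DegenerateDesignError(MetabometaError):
    """The regression design matrix is rank deficient.

    Carries the offending column names in ``columns``.
    """

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = list(columns or [])


class ParseError(MetabometaError):
    """A file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line
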