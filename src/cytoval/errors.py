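"""Exception hierarchy shared across the package."""


class CytovalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CytovalError):
    """A file does not conform to the expected on-disk format."""


class ParseError(FormatError):
    """A record inside a file could not be parsed; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"{message} (row {row})")


class ValidationError(CytovalError):
    """A value violates a documented precondition or invariant."""


class ConfigurationError(CytovalError):
    """A configuration object is internally inconsistent."""


class InsufficientDataError(CytovalError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(CytovalError):
    """The statistic is mathematically undefined for the given input."""


class QuantificationError(CytovalError):
    """A percentage cannot be formed (empty denominator)."""


class DegenerateDataError(CytovalError):
    """Input data admit no regression fit (e.g. all x identical)."""
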