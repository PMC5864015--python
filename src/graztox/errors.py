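"""Exception types shared across graztox modules."""


class GraztoxError(Exception):
    """Base class for all graztox errors."""


class ConfigurationError(GraztoxError, ValueError):
    """Raised when a user-supplied configuration value is invalid."""


class GridFormatError(GraztoxError, ValueError):
    """Raised when an ESRI ASCII grid file cannot be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(GraztoxError, ValueError):
    """Raised when a CSV table is missing required columns."""


class InvariantViolation(GraztoxError, RuntimeError):
    """Raised when simulation state violates a conservation invariant."""
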