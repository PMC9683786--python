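"""Exception hierarchy shared across the package."""


class SwimtrapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SwimtrapError, ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class DataError(SwimtrapError, ValueError):
    """Data violate a precondition (e.g. non-monotone timestamps)."""


class GeometryError(SwimtrapError, ValueError):
    """An operation requiring trap geometry was called without it."""


class ConfigError(SwimtrapError, ValueError):
    """An invalid or inconsistent configuration value."""


class SizeError(SwimtrapError, ValueError):
    """Input too short for the requested operation."""


class NumericalError(SwimtrapError, ArithmeticError):
    """Numerical breakdown (NaN/Inf) during integration; carries the step index."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
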