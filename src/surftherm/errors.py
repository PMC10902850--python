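"""Exception hierarchy for surftherm.

All domain errors derive from :class:`SurfthermError` so that callers (and the
CLI) can distinguish physics/input problems from programming errors.
"""


class SurfthermError(Exception):
    """Base class for all surftherm domain errors."""


class InvalidParameterError(SurfthermError, ValueError):
    """A physical parameter violates its invariant (e.g. T <= 0, v <= 0)."""


class UnderdeterminedFitError(SurfthermError):
    """Fewer data points than free parameters."""


class FitFailureError(SurfthermError):
    """The optimizer failed to converge; carries diagnostics in ``details``."""

    def __init__(self, message: str, details=None):
        super().__init__(message)
        self.details = details


class DivergenceError(SurfthermError):
    """A micelle-size series diverges (c1 above the CMC) and no override was given."""


class ExtrapolationError(SurfthermError):
    """A coverage lies outside the validity range of an equation of state or curve."""


class OutOfRangeError(SurfthermError):
    """No root bracket exists within the validity range."""


class AmbiguityError(SurfthermError):
    """Multiple self-consistent coverages found; ``roots`` lists all of them."""

    def __init__(self, message: str, roots=None):
        super().__init__(message)
        self.roots = tuple(roots or ())


class ParseError(SurfthermError):
    """Malformed row in a delimited table; carries the 1-based line number."""

    def __init__(self, message: str, line_number=None):
        super().__init__(message)
        self.line_number = line_number


class SchemaError(SurfthermError):
    """A table violates its schema (missing column, negative coverage, ...)."""
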