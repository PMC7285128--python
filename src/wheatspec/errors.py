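"""Exception hierarchy shared across the package."""


class WheatspecError(Exception):
    """Base class for all package errors."""


class SchemaError(WheatspecError):
    """A required column or field is missing from tabular input."""


class ValidationError(WheatspecError):
    """A record violates a domain invariant (range, type, uniqueness)."""


class UndefinedIndexError(WheatspecError):
    """A vegetation index is undefined for the given reflectances
    (zero denominator)."""


class DomainError(WheatspecError):
    """Input values lie outside the mathematical domain of an operation
    (e.g. non-positive response values for an exponential fit)."""


class DegenerateDataError(WheatspecError):
    """The data carry no usable variation (constant series, all-identical
    predictor, fewer distinct plots than a split requires)."""


class FitConvergenceError(WheatspecError):
    """Nonlinear least squares failed to converge.

    Carries the log-linear initializer coefficients so a caller can still
    inspect or reuse the closed-form fit.
    """

    def __init__(self, message: str, initializer: tuple[float, float]):
        super().__init__(message)
        self.initializer = initializer


class ConfigError(WheatspecError):
    """Invalid or contradictory configuration."""
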