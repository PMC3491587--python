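"""Exception and warning types shared across the package."""


class FruitfluxError(ValueError):
    """Base class for all package-specific errors."""


class ValidationError(FruitfluxError):
    """Malformed or out-of-range input data (row- or column-addressed)."""


class DomainError(FruitfluxError):
    """Argument outside the mathematical domain of an operation."""


class UndefinedConductanceError(DomainError):
    """Conductance inversion attempted with a non-positive driving force."""


class PairingError(FruitfluxError):
    """Flux intervals could not be paired with any weather records."""


class CoverageError(FruitfluxError):
    """Requested simulation or prediction window not covered by weather."""


class GapError(FruitfluxError):
    """Weather stream contains gaps longer than the configured maximum."""


class FitError(FruitfluxError):
    """Insufficient or degenerate data for a regression fit."""


class ComparisonError(FruitfluxError):
    """Too few positive pairs for a predicted-vs-measured comparison."""


class ExtrapolationWarning(UserWarning):
    """Conductance evaluated outside the fitted developmental range."""


class PercentileFallbackWarning(UserWarning):
    """BCa z-values unbounded; plain percentile interval returned instead."""


class InterpolationWarning(UserWarning):
    """A short weather gap was filled by linear interpolation."""


class ClampWarning(UserWarning):
    """Relative humidity slightly above 100 % was clamped to 100 %."""
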