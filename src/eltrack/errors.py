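"""Exception hierarchy shared across the package."""


class EltrackError(Exception):
    """Base class for all package errors."""


class SchemaError(EltrackError):
    """A cross-section table file violates the CSV schema or a table invariant."""


class EnergyRangeError(EltrackError):
    """Requested energy lies outside the tabulated span (no extrapolation)."""


class DomainError(EltrackError):
    """An argument lies outside the physical domain of an operation."""


class InsufficientDataError(EltrackError):
    """Too few points to perform a fit or decomposition."""


class NormalizationError(EltrackError):
    """A distribution cannot be normalized (zero total weight)."""


class ConfigError(EltrackError):
    """Invalid configuration or specification object."""
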