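"""Exception types shared across the package."""


class SegScreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SegScreenError, ValueError):
    """A file or table does not conform to the expected layout."""


class ValidationError(SegScreenError, ValueError):
    """A value violates a domain invariant (e.g. score out of range)."""


class DuplicateTreatmentError(ValidationError):
    """Two records share the same (compound, concentration, experiment) key."""


class ConfigError(SegScreenError, ValueError):
    """A configuration object is internally inconsistent."""


class InsufficientDataError(SegScreenError, ValueError):
    """Too few observations to compute the requested statistic."""


class UndefinedStatisticError(SegScreenError, ValueError):
    """The statistic is mathematically undefined for this input
    (e.g. correlation of a zero-variance margin)."""
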