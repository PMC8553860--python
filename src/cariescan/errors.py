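"""Exception hierarchy shared across the pipeline stages."""


class CariesScanError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CariesScanError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ConfigurationError(CariesScanError, ValueError):
    """A configuration object violates its invariants or is infeasible."""


class CohortValidationError(CariesScanError, ValueError):
    """A cohort file or table violates the cohort invariants."""


class ReferenceMissingError(CariesScanError):
    """A tooth lacks a sound reference for the requested condition."""


class InsufficientSignalError(CariesScanError):
    """Signals unusable for a ratio-based score (non-positive or absent)."""


class DegenerateLabelsError(CariesScanError, ValueError):
    """Both outcome classes are required but only one is present."""


class CalibrationError(CariesScanError):
    """Cut-off calibration is impossible for a requested level."""


class InsufficientTrainingError(CariesScanError):
    """Too few labeled sites per class to fit the scoring model."""
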