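"""Exception hierarchy shared across the pipeline."""


class DroughtVigorError(Exception):
    """Base class for package errors."""


class ConfigurationError(DroughtVigorError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DomainError(DroughtVigorError, ValueError):
    """An argument is outside the physical/mathematical domain of an operation."""


class ValidationError(DroughtVigorError, ValueError):
    """Input data violate a structural invariant (rejected at ingest)."""


class InconsistentGeometryError(ValidationError):
    """Ring widths imply a larger stem than the measured outer radius."""


class InsufficientOverlapError(ValidationError):
    """Two ring series overlap over fewer years than the correlation window."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested statistic."""


class DegenerateCurveError(DomainError):
    """A vulnerability curve carries no information about its midpoint (all 0 or all 100 PLC)."""


class UndefinedCorrelationError(DomainError):
    """Correlation requested on a zero-variance variable."""
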