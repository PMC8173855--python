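"""Exception hierarchy shared across the package."""


class CardioTwistError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CardioTwistError, ValueError):
    """Invalid parameter combination (rejected before any computation)."""


class DomainError(CardioTwistError, ValueError):
    """Arguments outside the mathematical domain of an operation."""


class QualityError(CardioTwistError, RuntimeError):
    """Signal quality too poor for a reliable estimate (e.g. no tag harmonic)."""


class TrackingQualityError(QualityError):
    """Contour tracking lost too many points."""


class EstimationError(CardioTwistError, RuntimeError):
    """A model fit failed or produced a physically inadmissible result."""
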