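"""Exception hierarchy shared across the package."""


class AortanormError(ValueError):
    """Base class for all package-specific errors."""


class DomainError(AortanormError):
    """An input value is outside its physical/mathematical domain."""


class IncompleteRecordError(AortanormError):
    """A record is missing a feature required by the requested operation."""


class DegenerateScaleError(AortanormError):
    """A feature is constant on the training cohort and cannot be scaled."""


class FitError(AortanormError):
    """Model fitting failed (too few records, rank deficiency, ...)."""


class DegenerateModelError(AortanormError):
    """A fitted model cannot produce the requested score (e.g. sigma = 0)."""


class ConfigurationError(AortanormError):
    """Mismatched or invalid configuration of models/ensembles."""


class PairingError(AortanormError):
    """Paired score sets do not refer to the same subjects/labels."""
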