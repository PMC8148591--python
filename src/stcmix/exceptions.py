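"""Exception hierarchy for stcmix.

All package errors derive from :class:`StcmixError` so callers can catch one
base class at pipeline boundaries.
"""


class StcmixError(Exception):
    """Base class for all stcmix errors."""


class ParameterError(StcmixError, ValueError):
    """A model or configuration parameter is outside its valid range."""


class DomainError(StcmixError, ValueError):
    """A requested effect level or concentration is outside the model's domain."""


class FitError(StcmixError, RuntimeError):
    """Curve fitting failed to converge.

    Carries the last iterate and solver diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateDataError(StcmixError, ValueError):
    """The data carry no usable signal (e.g. all-zero responses)."""


class NormalizationError(StcmixError, ValueError):
    """Control records are missing or unusable for an experiment."""


class DegenerateControlError(NormalizationError):
    """Control mean is zero; percent change is undefined."""


class DesignError(StcmixError, ValueError):
    """A mixture design is malformed (fractions, names, directions)."""


class MixedDirectionError(DesignError):
    """CA/IA prediction requested for components with opposing effect
    directions; such mixtures must go through the antagonism module."""


class ComparabilityError(StcmixError, ValueError):
    """Observed and reference concentration ranges do not overlap."""


class IngestionError(StcmixError, ValueError):
    """An input table is empty or lacks required columns."""
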