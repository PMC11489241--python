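"""Exception hierarchy for the scacoms package."""


class ScacomsError(Exception):
    """Base class for all package-specific errors."""


class RangeError(ScacomsError, ValueError):
    """A raw score falls outside its item's defined range."""


class ConfigError(ScacomsError, ValueError):
    """Scale configuration is missing, inconsistent, or incomplete."""


class ParseError(ScacomsError, ValueError):
    """A cohort file row could not be parsed."""


class IntegrityError(ScacomsError, ValueError):
    """Duplicate (subject, visit, item) observations or similar violations."""


class ParameterError(ScacomsError, ValueError):
    """Invalid simulation, power, or validation parameters."""


class DerivationError(ScacomsError, RuntimeError):
    """Composite derivation failed (e.g. every candidate was removed)."""


class ScoringError(ScacomsError, ValueError):
    """Composite scoring failed (e.g. a retained item is missing)."""


class AnalysisError(ScacomsError, RuntimeError):
    """A downstream statistic is undefined (zero SD, degenerate fit, ...)."""
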