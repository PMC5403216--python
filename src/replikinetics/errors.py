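"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`ReplikineticsError`, so callers can
distinguish bad inputs from fit failures and genuinely unidentifiable
estimates (e.g. a track time at or above the bleach time).
"""


class ReplikineticsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ReplikineticsError, ValueError):
    """A simulation or model parameter violates its invariants."""


class InputError(ReplikineticsError, ValueError):
    """Input data violates a precondition (unsorted table, duration < L, ...)."""


class ConfigurationError(ReplikineticsError, ValueError):
    """A configuration value is missing or inconsistent."""


class FitError(ReplikineticsError, RuntimeError):
    """An estimator failed to converge or the input is degenerate."""


class UninformativeEstimateError(ReplikineticsError, RuntimeError):
    """The bound time is not identifiable (track time >= bleach time)."""


class InsufficientDataError(ReplikineticsError, ValueError):
    """Not enough observations to run the requested analysis."""
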