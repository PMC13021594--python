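"""Exception hierarchy for swaylab.

All errors raised by the package derive from :class:`SwaylabError` so callers
can catch the whole family with one clause.
"""


class SwaylabError(Exception):
    """Base class for all swaylab errors."""


class FormatError(SwaylabError):
    """Raised when an input file violates the expected tabular layout."""


class ConfigError(SwaylabError):
    """Raised when a schema or configuration is incomplete or inconsistent."""


class ParameterError(SwaylabError):
    """Raised for invalid numeric parameters (even kernel, non-positive mass, ...)."""


class InputError(SwaylabError):
    """Raised when a signal is too short or otherwise unusable."""


class DegenerateInputError(SwaylabError):
    """Raised for degenerate data (zero-variance weight, non-positive ratio base)."""


class DesignError(SwaylabError):
    """Raised when a filter specification cannot be met."""


class FitError(SwaylabError):
    """Raised when a model fit has too few points to proceed."""


class CalibrationError(SwaylabError):
    """Raised when simulator calibration fails to converge.

    Carries the best parameters found so far and the residuals so callers can
    inspect or continue from them.
    """

    def __init__(self, message, params=None, residuals=None):
        super().__init__(message)
        self.params = params
        self.residuals = residuals


class BalanceError(SwaylabError):
    """Raised when age-distribution balancing is impossible in some stratum."""
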