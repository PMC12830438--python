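"""Exception types shared across the package.

All statistical routines distinguish *undefined* results (zero variance,
degenerate inputs) from ordinary numeric NaN so that callers can audit
how often a quantity failed to exist rather than silently propagating NaN.
"""


class RsvpDiError(Exception):
    """Base class for package errors."""


class ConfigurationError(RsvpDiError):
    """Invalid or infeasible generator / pipeline configuration."""


class UndefinedResultError(RsvpDiError):
    """A statistic does not exist for the given input (e.g. zero variance)."""


class InvalidTrialError(RsvpDiError):
    """A trial violates the task's structural rules (e.g. target == post-target)."""


class ValidationError(RsvpDiError):
    """A table failed schema validation; message lists offending rows."""


class NumericalError(RsvpDiError):
    """A quadrature or root-finding routine failed to converge."""


class SampleSizeCapError(RsvpDiError):
    """A sample-size search exceeded its configured cap."""

    def __init__(self, cap: int, message: str | None = None):
        self.cap = cap
        super().__init__(message or f"required sample size exceeds cap of {cap}")
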