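"""Exception hierarchy.

Validation errors signal contract violations on inputs, format errors a
malformed file, numerical errors a diverging optimisation.  The CLI maps
each family to a distinct exit code.
"""


class CDIError(Exception):
    """Base class for all package errors."""


class ValidationError(CDIError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(CDIError, IOError):
    """A file does not follow the expected on-disk layout."""


class NoCandidatesError(ValidationError):
    """No eligible pixels remain (e.g. exclusion zone covers everything)."""


class UndefinedMetricError(ValidationError):
    """A figure of merit is undefined for the given input (empty subset,
    zero total power)."""


class NumericalDivergenceError(CDIError, RuntimeError):
    """Non-finite values appeared during iterative phasing."""

    def __init__(self, message: str, cycle: int | None = None):
        super().__init__(message)
        self.cycle = cycle


class RegistrationError(CDIError, RuntimeError):
    """Sub-pixel registration could not be performed (zero-power input)."""


class ConsistencyError(ValidationError):
    """Solutions being compared were scored against different free masks."""
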