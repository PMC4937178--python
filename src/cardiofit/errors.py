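"""Exception hierarchy.

All input validation raises :class:`ValidationError`, which the CLI maps to
exit code 2.  Internal invariant breaches raise plain exceptions and are bugs.
"""


class CardioFitError(Exception):
    """Base class for all package errors."""


class ValidationError(CardioFitError, ValueError):
    """Raised when user-supplied data violates a documented precondition."""


class CoverageError(ValidationError):
    """Raised when a heart-rate trace does not cover a required analysis window."""
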