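"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 1 (bad input or configuration),
``NumericalError`` to exit code 2 (a computation that could not be completed).
"""


class SigsurvError(Exception):
    """Base class for all package errors."""


class ValidationError(SigsurvError, ValueError):
    """Invalid input data or configuration."""


# configuration problems are a species of validation problem
ConfigurationError = ValidationError


class NumericalError(SigsurvError, RuntimeError):
    """A numerical procedure failed (non-convergence, degenerate problem)."""
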