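"""Exception hierarchy shared across the package.

The CLI maps :class:`ValidationError` to exit code 2 and
:class:`NumericalError` to exit code 3.
"""


class CrossdecompError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CrossdecompError, ValueError):
    """Raised when an input violates a documented precondition or invariant."""


class NumericalError(CrossdecompError, RuntimeError):
    """Raised when a numerical routine fails (singularity, non-convergence)."""
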