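"""Exception hierarchy.

``InvalidInputError`` marks malformed user input (CLI exit code 1);
everything else derives from ``VennoseError`` (CLI exit code 2).
"""


class VennoseError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VennoseError, ValueError):
    """Malformed or inconsistent user-supplied input."""


class ParseError(InvalidInputError):
    """A file could not be parsed; message names the offending location."""


class ConvergenceError(VennoseError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, *, gradient_norm: float | None = None,
                 iterations: int | None = None):
        super().__init__(message)
        self.gradient_norm = gradient_norm
        self.iterations = iterations


class NotFittedError(VennoseError):
    """A model was used before being fitted."""
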