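"""Exception hierarchy shared across the package."""


class TopoHiCError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TopoHiCError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(TopoHiCError):
    """Input violated a documented precondition."""


class BoundsError(ValidationError):
    """A coordinate or bin index fell outside the addressable range."""


class ConvergenceError(TopoHiCError):
    """An iterative procedure failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)
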