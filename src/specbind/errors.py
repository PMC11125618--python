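"""Exception hierarchy shared across the package."""


class SpecbindError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SpecbindError):
    """A text input could not be parsed; message names the offending line/cell."""


class ValidationError(SpecbindError):
    """An input violates a documented precondition or type invariant."""


class InsufficientDataError(SpecbindError):
    """Too few usable points for the requested operation."""


class FitError(SpecbindError):
    """A nonlinear fit failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual
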