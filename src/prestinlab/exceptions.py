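"""Exception types shared across the package."""


class PrestinLabError(Exception):
    """Base class for package errors."""


class DomainError(PrestinLabError, ValueError):
    """Input outside the mathematical/physical domain of an operation."""


class FitError(PrestinLabError, RuntimeError):
    """Nonlinear fit failed or the data cannot constrain the model.

    Carries a ``diagnostics`` dict (last iterate, message) when available.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class GridMismatchError(PrestinLabError, ValueError):
    """Spectra (or traces) with incompatible sampling grids were combined."""


class ParseError(PrestinLabError, ValueError):
    """Malformed data or configuration file; message includes location."""
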