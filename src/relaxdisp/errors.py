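"""Exception hierarchy shared across the package."""


class RelaxDispError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(RelaxDispError):
    """A measured record is physically impossible (e.g. non-positive intensity)."""


class ConfigurationError(RelaxDispError):
    """An acquisition or run configuration is internally inconsistent."""


class NumericalFitError(RelaxDispError):
    """A numerical fit failed or was handed degenerate data."""


class FitFailureError(RelaxDispError):
    """A parameter optimization did not converge; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
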