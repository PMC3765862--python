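"""Exception types shared across the package."""


class PhysupplyError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PhysupplyError, ValueError):
    """A numeric argument is outside its admissible range (negative rate, dt <= 0, ...)."""


class ConfigurationError(PhysupplyError, ValueError):
    """Model wiring or parameter coverage is inconsistent (missing quota years, bad fractions, ...)."""


class InvalidScenarioError(ConfigurationError):
    """A scenario perturbation drives a parameter outside its admissible range."""


class CalibrationError(PhysupplyError, RuntimeError):
    """The calibration optimizer failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
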