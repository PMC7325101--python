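"""Exception hierarchy used across the package."""


class PiburdenError(Exception):
    """Base class for all package errors."""


class ArgumentError(PiburdenError, ValueError):
    """A caller supplied an out-of-range or malformed argument."""


class ConfigError(PiburdenError):
    """A configuration file or parameter set failed validation."""


class FixtureError(PiburdenError):
    """A packaged data fixture is missing or corrupt."""


class CalibrationError(PiburdenError):
    """The calibration loop failed to converge within ``max_iter``."""

    def __init__(self, message: str, worst_residual: float | None = None):
        super().__init__(message)
        self.worst_residual = worst_residual


class StructuralInfeasibilityError(CalibrationError):
    """A positive target stream that the model structurally cannot produce."""
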