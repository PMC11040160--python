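"""Exception types raised across the package."""


class CsmKineticsError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(CsmKineticsError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class InvalidParameterError(CsmKineticsError, ValueError):
    """A model parameter is outside its admissible range."""


class DegenerateTraceError(CsmKineticsError, ValueError):
    """An intensity trace cannot be correlated (e.g. zero mean channel)."""


class DegenerateControlError(CsmKineticsError, ValueError):
    """A control series is unusable for normalization (non-positive values)."""


class FitFailureError(CsmKineticsError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostic detail."""

    def __init__(self, message, residual_norm=None):
        super().__init__(message)
        self.residual_norm = residual_norm


class IdentifiabilityError(CsmKineticsError, ValueError):
    """The requested fit is under-determined by the supplied data."""


class CalibrationError(CsmKineticsError, ValueError):
    """Signal calibration failed (insufficient points or non-positive scale)."""


class SimulationError(CsmKineticsError, RuntimeError):
    """Numerical integration of the kinetic model failed."""
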