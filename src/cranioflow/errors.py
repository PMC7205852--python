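"""Exception hierarchy."""


class CranioflowError(Exception):
    """Base class for all package errors."""


class DomainError(CranioflowError, ValueError):
    """An argument is outside the physical domain of a constitutive law."""


class CurveFormatError(CranioflowError, ValueError):
    """A curve file or SampledCurve violates the expected format."""


class IntegrationError(CranioflowError):
    """The ODE integrator failed; carries the last valid state and time."""

    def __init__(self, message, last_time=None, last_state=None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


class EquilibriumError(CranioflowError):
    """The constant-inflow equilibrium root finder did not converge."""


class ConvergenceError(CranioflowError):
    """Periodic steady state was not reached; carries the residual history."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class FitError(CranioflowError):
    """Calibration failed (e.g. every objective evaluation diverged)."""
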