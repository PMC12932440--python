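"""Exception hierarchy for osteomeno."""


class OsteomenoError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OsteomenoError, ValueError):
    """An argument violates a mathematical precondition (sign, range)."""


class ModelEvaluationError(OsteomenoError, ArithmeticError):
    """The model right-hand side produced a non-finite value."""


class ConvergenceError(OsteomenoError, RuntimeError):
    """An iterative solve failed to reach the requested residual tolerance."""


class IntegrationError(OsteomenoError, RuntimeError):
    """The ODE integrator failed; carries the time of failure when known."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class CurationError(OsteomenoError, ValueError):
    """A BMD study dataset cannot be curated (schema or onset problems)."""
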