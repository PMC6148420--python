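"""Exception hierarchy for corvgrowth."""


class CorvgrowthError(Exception):
    """Base class for all package errors."""


class ParameterError(CorvgrowthError):
    """A parameter record does not match the model, or violates an invariant."""


class UnsupportedCaseError(CorvgrowthError):
    """A degenerate curve family that is deliberately not implemented
    (Schnute with a = 0 or b = 0; Schnute-Richards with b = 0)."""


class InputError(CorvgrowthError):
    """Invalid user-supplied data or configuration."""


class DomainError(CorvgrowthError):
    """A quantity is requested outside its mathematical domain
    (e.g. the AICc correction with n <= k + 1)."""


class FitConvergenceError(CorvgrowthError):
    """No restart of a nonlinear fit converged.

    Carries the best (non-converged) attempt on ``best_attempt`` so the
    caller can inspect it.
    """

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class ExperimentError(CorvgrowthError):
    """A Monte-Carlo experiment failed systematically (e.g. >50% of
    replicates did not converge). Carries diagnostics on ``diagnostics``."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
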