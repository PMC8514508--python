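"""Exception hierarchy shared across the package."""


class FraclakeError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FraclakeError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(FraclakeError, ValueError):
    """Input data or configuration violates a documented contract."""


class SeriesConvergenceError(FraclakeError, ArithmeticError):
    """The Mittag-Leffler power series diverged or is ill-conditioned
    within the allowed number of terms."""


class QuadratureError(FraclakeError, ArithmeticError):
    """Adaptive quadrature failed to reach the requested tolerance.

    Carries the tolerance actually achieved in ``achieved_rel_tol``.
    """

    def __init__(self, message: str, achieved_rel_tol: float):
        super().__init__(message)
        self.achieved_rel_tol = achieved_rel_tol


class FitNonConvergence(FraclakeError, RuntimeError):
    """A model fit terminated without meeting its convergence criteria."""
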