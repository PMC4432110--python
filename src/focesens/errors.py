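"""Exception hierarchy for model validation, integration and estimation."""


class FocesensError(Exception):
    """Base class for all package errors."""


class ValidationError(FocesensError):
    """A model declaration violates the symbol-closure or structural rules."""


class UnsupportedExpressionError(FocesensError):
    """An expression cannot be differentiated (discontinuous construct etc.)."""


class DomainError(FocesensError):
    """An argument is outside its mathematical domain (negative counts etc.)."""


class NumericDomainError(FocesensError):
    """A covariance matrix failed a positive-definiteness check.

    The message names the offending matrix (Omega or R).
    """


class IntegrationError(FocesensError):
    """The ODE solver failed; carries the time of failure."""

    def __init__(self, message, t=None):
        super().__init__(message)
        self.t = t


class InnerFailureError(FocesensError):
    """The inner optimization did not converge; carries the best iterate."""

    def __init__(self, message, best_eta=None, best_value=None):
        super().__init__(message)
        self.best_eta = best_eta
        self.best_value = best_value


class ObjectiveFailure(FocesensError):
    """Evaluation of log L_F failed at this theta (inner failure or a
    non-positive-definite -H_i).  Reported, not fatal: the outer line
    search backtracks on it."""


class GradientFailure(FocesensError):
    """A per-individual gradient computation failed; names the individual."""


class PreconditionError(FocesensError):
    """A routine was called with stale inputs (e.g. a non-stationary eta*)."""


class FitFailure(FocesensError):
    """The outer optimization failed; carries the diagnostic trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class ParseError(FocesensError):
    """A dataset row or config entry could not be parsed; names the row."""
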