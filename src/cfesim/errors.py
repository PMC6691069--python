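"""Exception hierarchy."""


class CfesimError(Exception):
    """Base class for all package errors."""


class FormatError(CfesimError):
    """Malformed input file (missing columns, unknown labels, bad syntax)."""


class ValidationError(CfesimError):
    """Input violates a domain invariant (units, ranges, mesh conformity)."""


class FitError(CfesimError):
    """Optimizer failed to converge; carries the best parameters seen."""

    def __init__(self, message, best_params=None, residual=None):
        super().__init__(message)
        self.best_params = best_params
        self.residual = residual


class SolverError(CfesimError):
    """Linear or nonlinear solve failed; may carry a residual history."""

    def __init__(self, message, residual_history=None, state=None):
        super().__init__(message)
        self.residual_history = residual_history
        self.state = state
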