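"""Exception hierarchy.

Errors are split so that callers (and the CLI exit-code mapping) can
distinguish bad configuration, malformed input data, and numerical failure
of a per-study fit.
"""


class FPMetaError(Exception):
    """Base class for all package errors."""


class ValidationError(FPMetaError, ValueError):
    """Invalid argument or configuration (wrong power, bad centiles, ...)."""


class DomainError(FPMetaError, ValueError):
    """Input value outside the mathematical domain of a transformation."""


class SchemaError(FPMetaError, ValueError):
    """Malformed input table (missing column, non-numeric field, ...)."""


class FitError(FPMetaError, RuntimeError):
    """A per-study model fit failed."""


class ConvergenceError(FitError):
    """Newton-Raphson did not converge; carries the last iterate."""

    def __init__(self, message, beta=None, loglik=None, n_iter=None):
        super().__init__(message)
        self.beta = beta
        self.loglik = loglik
        self.n_iter = n_iter


class RankError(FitError):
    """Singular information matrix (collinear design, empty category, ...)."""
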