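"""Exception hierarchy shared by all pipeline stages."""


class HybridBlupError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HybridBlupError, ValueError):
    """A configuration value violates its documented domain."""


class DataError(HybridBlupError, ValueError):
    """Input data are inconsistent with what the operation requires."""


class FitError(HybridBlupError, RuntimeError):
    """Model fitting failed to converge; carries the best point found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class NumericalError(HybridBlupError, ArithmeticError):
    """A linear-algebra step failed (singular or ill-conditioned system)."""
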