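"""Exception types shared across the package."""


class AbosimError(Exception):
    """Base class for all package-specific errors."""


class InvalidFrequencyError(AbosimError, ValueError):
    """A frequency vector is outside the simplex (negative, >1, or bad sum)."""


class DegeneratePopulationError(AbosimError, ArithmeticError):
    """Mean fitness is zero, so post-selection frequencies cannot be formed."""


class ConvergenceError(AbosimError, RuntimeError):
    """Fixed-point iteration did not converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class InsufficientDataError(AbosimError, ValueError):
    """Too few usable records for the requested estimate."""


class DegenerateDesignError(AbosimError, ValueError):
    """Regression design has no variance in the predictor."""


class SchemaError(AbosimError, ValueError):
    """A delimited input table is missing required columns."""
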