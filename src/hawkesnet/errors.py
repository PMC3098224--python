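"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A generator or analysis was called with invalid parameters."""


class DegenerateNetworkError(ValueError):
    """A network statistic is undefined for this topology (e.g. zero variance)."""


class DivergenceError(ArithmeticError):
    """The covariance power series diverges (spectral radius >= 1)."""


class StabilityError(ArithmeticError):
    """(I - G) is singular or the linear dynamics has no stable equilibrium."""


class EstimatorError(ValueError):
    """Spike-train statistics were requested from insufficient data."""
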