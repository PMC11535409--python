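"""Exception types shared across the package."""


class GeometryError(ValueError):
    """Degenerate or self-intersecting geometry."""


class ParameterError(ValueError):
    """Invalid model parameter."""


class SchemaError(ValueError):
    """Feature table or model file does not match the documented schema."""


class UnderdeterminedError(ValueError):
    """Balance system has no interior vertex equations."""


class EquilibrationError(RuntimeError):
    """Relaxation failed to reach the requested force residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class StatisticsError(ValueError):
    """Undefined statistic (zero variance, empty group, ...)."""
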