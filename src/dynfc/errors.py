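"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter is outside its mathematical or physical domain."""


class InvalidInputError(ValueError):
    """Input data violate a precondition (shape, length, finiteness)."""


class DegenerateSeriesError(ValueError):
    """A time series carries no usable signal (constant, all-zero)."""


class EstimationError(RuntimeError):
    """An estimator could not produce a value from the given data."""
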