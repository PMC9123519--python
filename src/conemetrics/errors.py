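"""Exception types shared across the package."""


class ConemetricsError(Exception):
    """Base class for all package errors."""


class ParameterError(ConemetricsError, ValueError):
    """A configuration or argument value is invalid (non-positive scale,
    out-of-range fraction, singular transform, ...)."""


class UndefinedMetricError(ConemetricsError, ValueError):
    """A point-pattern metric is undefined for the given input, e.g. fewer
    than three non-collinear points or no bound Voronoi cells in the ROI."""
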