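"""Exception hierarchy used across the package.

All errors derive from :class:`FluxMetaError` (a ``ValueError``) so callers
can catch package failures with a single except clause.
"""


class FluxMetaError(ValueError):
    """Base class for all package-specific errors."""


class ParameterError(FluxMetaError):
    """Invalid generator or model parameters."""


class ConfigurationError(FluxMetaError):
    """Inconsistent run configuration (empty task sets, bad arch, ...)."""


class SchemaError(FluxMetaError):
    """Input data does not match the expected schema or shapes."""


class GeometryError(FluxMetaError):
    """Grid extents, resolutions or shapes do not conform."""


class DegenerateFeatureError(FluxMetaError):
    """A feature has zero variance and cannot be z-normalized."""


class DivergenceError(FluxMetaError):
    """Training produced a non-finite loss."""


class PeriodError(FluxMetaError):
    """A time axis does not cover whole months/years as required."""


class SampleSizeError(FluxMetaError):
    """Too few samples for the requested statistic."""
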