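"""Typed exceptions raised across the pipeline."""


class LurError(Exception):
    """Base class for all package errors."""


class ConfigError(LurError):
    """Invalid study or pipeline configuration."""


class SiteGenerationError(LurError):
    """Site sampling could not satisfy a placement constraint."""


class SchedulingError(LurError):
    """Measurement schedule is infeasible for the configured capacity."""


class GeometryAggregationError(LurError):
    """Layer geometry type is incompatible with the requested aggregation."""


class EmptyLayerError(LurError):
    """Operation requires a non-empty feature layer."""


class MissingLayerError(LurError):
    """A predictor references a layer category that was not provided."""


class DuplicatePredictorError(LurError):
    """Two predictor specs share the same name."""


class RasterCoverageError(LurError):
    """A buffer extends beyond the raster extent."""


class EmptyMatrixError(LurError):
    """Predictor matrix has no rows or no columns."""


class AllMissingError(LurError):
    """A time series contains no observed values at all."""


class RankDeficientError(LurError):
    """A regression design matrix is rank deficient."""


class SeasonWindowError(LurError):
    """A measurement week falls outside its season window."""


class FoldError(LurError):
    """A cross-validation fold could not be fitted."""


class ZeroVarianceError(LurError):
    """Residuals have zero variance; the statistic is undefined."""
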