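"""Exception hierarchy for the fundus-age pipeline.

Every failure mode that the pipeline reports per-eye (rather than crashing on)
derives from :class:`FundusError`, so orchestration code can catch one type and
record the eye in an exclusion sidecar.
"""


class FundusError(Exception):
    """Base class for all pipeline-specific errors."""


class InvalidLandmarksError(FundusError):
    """Landmark set violates its contract (e.g. fewer than 8 disc boundary points)."""


class DegenerateGeometryError(FundusError):
    """Geometric computation is undefined (zero-width disc, crossing at disc center)."""


class UndefinedTemporalError(DegenerateGeometryError):
    """Fovea lies vertically in line with the disc center; temporal side undefined."""


class OutOfBoundsError(FundusError):
    """A sampling ROI extends outside the image raster."""


class UndefinedTFIError(FundusError):
    """Tessellation fundus index undefined because R + G + B == 0."""


class DegenerateFeatureError(FundusError):
    """A feature column is constant and cannot be standardized."""


class UndefinedCorrelationError(FundusError):
    """Pearson correlation undefined for a constant vector."""


class SchemaError(FundusError):
    """An input file does not match the documented schema."""


class RenderError(FundusError):
    """Synthetic render geometry does not fit inside the requested frame."""
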