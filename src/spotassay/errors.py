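"""Exception hierarchy for the spot-assay pipeline.

All domain errors derive from :class:`SpotAssayError` so callers (and the
CLI driver) can catch pipeline failures without swallowing programming
errors.
"""


class SpotAssayError(Exception):
    """Base class for all domain errors raised by this package."""


class InvalidParameterError(SpotAssayError, ValueError):
    """A scalar parameter violates its precondition."""


class LayoutError(SpotAssayError, ValueError):
    """Plate layout is inconsistent or its capacity is exceeded."""


class UnsupportedImageError(SpotAssayError, ValueError):
    """Image is not 8-bit greyscale/RGB raster data."""


class ROIError(SpotAssayError, ValueError):
    """A circular region of interest does not fit inside the image."""


class InsufficientDataError(SpotAssayError, ValueError):
    """Too few points/replicates/pairs for the requested computation."""


class UnitError(SpotAssayError, ValueError):
    """Concentration units are mixed within one curve or sample."""


class MissingBlankError(SpotAssayError, ValueError):
    """A required blank (reagent or extract) response is unavailable."""


class DegenerateRangeError(SpotAssayError, ValueError):
    """Response range is degenerate (max response not above blank)."""


class InvalidControlError(SpotAssayError, ValueError):
    """Control absorbance is non-positive."""


class InvalidSlopeError(SpotAssayError, ValueError):
    """Calibration slope is non-positive."""


class UndefinedCVError(SpotAssayError, ValueError):
    """Coefficient of variation undefined (zero mean)."""


class DesignError(SpotAssayError, ValueError):
    """Calibration design is degenerate (e.g. a single level)."""


class DegenerateRegressionError(SpotAssayError, ValueError):
    """Regression undefined (zero variance in the predictor)."""


class SchemaError(SpotAssayError, ValueError):
    """A CSV/config file violates the documented schema."""


class PipelineError(SpotAssayError, RuntimeError):
    """A pipeline stage failed; message names the stage and record."""
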