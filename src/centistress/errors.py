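"""Exception hierarchy.

Every error raised by the package derives from :class:`CentistressError` so
callers (and the CLI) can map failures to stages and exit codes.
"""


class CentistressError(Exception):
    """Base class for all package errors."""


class GeometryError(CentistressError):
    """Phantom compartments overlap, fall outside the grid, or are empty."""


class DegenerateSubjectError(CentistressError):
    """Atrophy morphing emptied a required region."""


class ModelParameterError(CentistressError):
    """Uptake-model parameters produced a non-positive region intensity."""


class CannotSharpenError(CentistressError):
    """Harmonization target resolution is finer than the current one."""


class MaskError(CentistressError):
    """A required region mask is missing or empty."""


class TransformError(CentistressError):
    """Non-invertible or otherwise unusable spatial transform."""


class AlignmentError(CentistressError):
    """Image and mask grids do not match."""


class MeasurementError(CentistressError):
    """Invalid SUVr measurement (e.g. non-positive reference mean)."""


class CalibrationError(CentistressError):
    """Invalid Centiloid anchors or calibration inputs."""


class FitError(CentistressError):
    """A regression fit is not identifiable (e.g. zero predictor variance)."""


class StratificationError(CentistressError):
    """A subject lacks the standard-pipeline record needed for stratification."""


class InsufficientDataError(CentistressError):
    """Too few observations for the requested statistic."""


class InterpolationError(CentistressError):
    """Degenerate anchors for confidence-interval interpolation."""


class ConfigError(CentistressError):
    """Invalid run configuration or missing calibration entries."""


class StageError(CentistressError):
    """Wraps a failure inside a named stage of the end-to-end run."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
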