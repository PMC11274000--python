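"""Exception hierarchy for the silhouette-morphometry pipeline."""


class OvimorphError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(OvimorphError, ValueError):
    """Input violates a documented precondition."""


class EmptyMaskError(ValidationError):
    """A silhouette operation received a mask with no foreground pixels."""


class DegenerateGeometryError(ValidationError):
    """Point set is degenerate (collinear / too few points) for the
    requested geometric construction."""


class LandmarkNotFoundError(OvimorphError):
    """An anatomical feature point could not be located on the contour."""


class UnsupportedPostureError(OvimorphError):
    """Body measures were requested for a posture they are not defined in
    (jumping frames are excluded from measurement)."""


class CalibrationError(OvimorphError):
    """Calibration fit or evaluation failed."""


class NonPhysicalCalibrationError(CalibrationError):
    """The pixel-per-centimeter ratio is non-positive, i.e. the model was
    evaluated outside its physically calibrated range."""


class UndefinedMetricError(OvimorphError, ZeroDivisionError):
    """Precision/recall denominator is zero."""
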