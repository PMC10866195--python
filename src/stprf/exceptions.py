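"""Exception hierarchy for the stprf package."""


class StprfError(Exception):
    """Base class for all stprf errors."""


class InvalidDesignError(StprfError):
    """A stimulus design is internally inconsistent (bad step/angle, geometry)."""


class ScheduleOverflowError(InvalidDesignError):
    """A temporal on/ISI schedule does not fit inside its bar-location slot."""


class InvalidScheduleError(InvalidDesignError):
    """A run schedule does not cover every bar location with a condition."""


class ParameterError(StprfError, ValueError):
    """A model parameter is outside its admissible domain."""


class ShapeError(StprfError, ValueError):
    """Array shapes or grids do not match."""


class SingularDesignError(StprfError):
    """A GLM design matrix is rank deficient."""


class CalibrationError(StprfError):
    """Noise cannot be calibrated (e.g., zero-variance signal)."""
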