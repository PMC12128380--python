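"""Exception hierarchy for spdefmeth."""


class SpdefmethError(Exception):
    """Base class for all package errors."""


class ConfigError(SpdefmethError):
    """Invalid generator or pipeline configuration."""


class InvalidSampleError(SpdefmethError):
    """A qPCR measurement cannot yield a methylation call
    (e.g. no amplifiable input DNA in the undigested arm)."""


class InvalidLaneError(SpdefmethError):
    """A gel lane has no usable undigested reference band."""


class InsufficientStandardsError(SpdefmethError):
    """Fewer than three positive-level calibration standards."""


class UndefinedRocError(SpdefmethError):
    """ROC analysis requires both classes to be present."""


class UndefinedCorrelationError(SpdefmethError):
    """Correlation is undefined when a variable has zero variance."""


class DegenerateDesignError(SpdefmethError):
    """Regression design matrix is rank-deficient (constant predictor)."""


class CalibrationError(SpdefmethError):
    """A calibration target is unreachable within parameter bounds.

    The message names the offending target and reports the achievable
    range, so a failed calibration is diagnosable rather than silent.
    """


class SchemaError(SpdefmethError):
    """An input table does not conform to its declared schema."""
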