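"""Exception hierarchy for corneapuff.

Every error raised by the library derives from :class:`CorneaPuffError`,
so callers can catch the whole family with one clause while the pipeline
records the specific failure reason per metric.
"""


class CorneaPuffError(Exception):
    """Base class for all corneapuff errors."""


class InvalidSpecError(CorneaPuffError, ValueError):
    """A generator or experiment specification violates its invariants."""


class InvalidParameterError(CorneaPuffError, ValueError):
    """A physical parameter is outside its admissible range (e.g. k <= 0)."""


class InvalidTraceError(CorneaPuffError, ValueError):
    """A time series is malformed (non-increasing time, NaNs, length mismatch)."""


class OutOfRangeError(CorneaPuffError, ValueError):
    """A rendered surface would fall outside the image depth range."""


class SegmentationFailureError(CorneaPuffError, RuntimeError):
    """Too many A-scan columns had no detectable surface."""


class NoSurfaceError(SegmentationFailureError):
    """The image contains no interface at all (e.g. uniform background)."""


class InvalidWindowError(CorneaPuffError, ValueError):
    """A baseline/analysis window is empty or has too few valid samples."""


class NoRecoveryError(CorneaPuffError, RuntimeError):
    """No post-peak samples satisfy the recovery criterion |x| < 5% MAD."""


class AlignmentError(CorneaPuffError, ValueError):
    """Displacement and force traces have non-overlapping time support."""


class NoDeformationError(CorneaPuffError, ValueError):
    """Maximum apex displacement is not positive; no loop can be built."""


class InsufficientDataError(CorneaPuffError, ValueError):
    """Too few samples for the requested integral or fit."""


class UndefinedRatioError(CorneaPuffError, ValueError):
    """Hysteresis ratio is undefined because loading energy is zero."""


class SlopeUndefinedError(CorneaPuffError, ValueError):
    """A slope descriptor cannot be computed on this loading curve."""


class InsufficientWindowError(SlopeUndefinedError):
    """The 120 um fitting window does not fit inside the loading span."""


class DegenerateDesignError(CorneaPuffError, ValueError):
    """Calibration design matrix is singular (all pressures identical)."""


class UndefinedStatisticError(CorneaPuffError, ValueError):
    """A test statistic or correlation is undefined for the given samples."""
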