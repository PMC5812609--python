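"""Exception hierarchy for the ibsa package.

Every error raised by the library derives from :class:`IbsaError`, so callers
(including the CLI) can distinguish domain failures from programming errors.
"""


class IbsaError(Exception):
    """Base class for all ibsa domain errors."""


class FormatError(IbsaError):
    """Unreadable or unsupported image file."""


class InconsistentSeriesError(FormatError):
    """DICOM series with missing, duplicated or irregular slice positions."""


class MultipleSeriesError(FormatError):
    """Directory mixes files from more than one DICOM series."""


class GeometryMismatchError(IbsaError):
    """Mask and reference volume have incompatible dimensions."""


class SliceOutOfRangeError(IbsaError):
    """Requested slice index outside the volume."""


class NoBodyFoundError(IbsaError):
    """Segmentation produced no acceptable body component."""


class EmptyMaskError(IbsaError):
    """Operation requires a nonempty mask."""


class InvalidExtentError(IbsaError):
    """Zero or negative z-extent where a positive one is required."""


class ImplausibleAnthropometricsError(IbsaError):
    """Height/weight outside the supported human range."""


class UnknownModelError(IbsaError):
    """BSA model name not recognised."""


class InvalidTruthError(IbsaError):
    """Reference surface must be strictly positive."""


class InsufficientDataError(IbsaError):
    """Not enough observations for the requested statistic."""


class InvalidValuesError(IbsaError):
    """Nonpositive values where proportional differences are requested."""


class DegenerateDataError(IbsaError):
    """Statistic undefined on the given data (e.g. zero variance everywhere)."""


class InvalidBandTableError(IbsaError):
    """Dose-band table violates contiguity/ordering constraints."""


class PhantomOutOfBoundsError(IbsaError):
    """Requested solid does not fit inside the phantom grid with margin."""


class OutOfFieldError(IbsaError):
    """Rigid transform pushed the body outside the field of view."""
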