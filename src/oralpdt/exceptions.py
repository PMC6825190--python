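"""Exception and warning types shared across the package."""


class OralPdtError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(OralPdtError, ValueError):
    """A parameter violates its documented constraints."""


class InvalidRoiError(OralPdtError, ValueError):
    """The region-of-interest seed is empty or outside the frame."""


class FormatError(OralPdtError, ValueError):
    """Unreadable input, or frames of inconsistent shape."""


class EmptyInputError(FormatError):
    """A frame directory or record list contained no data."""


class OutOfBoundsError(OralPdtError, ValueError):
    """A marker position falls outside the frame; carries the frame index."""

    def __init__(self, frame_index: int, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(message or f"marker outside frame bounds at frame {frame_index}")


class InvalidFrameError(OralPdtError):
    """A single frame could not yield a marker centroid (batch tracking flags it)."""


class TrackingFailureError(OralPdtError):
    """More than half of the analysed frames failed to yield a centroid."""


class InsufficientDataError(OralPdtError, ValueError):
    """Fewer valid observations than the statistic requires."""


class EmptyGroupError(OralPdtError, ValueError):
    """A cohort/survey group selection matched no records."""


class EmptyLesionError(OralPdtError):
    """Lesion segmentation found no above-threshold pixels."""


class RegistrationError(OralPdtError, ValueError):
    """Pre/post fluorescence images disagree in size."""


class SurveyValidationError(OralPdtError, ValueError):
    """A comfort-survey table has out-of-range, non-integer or duplicated rows."""


class DegenerateClusteringWarning(UserWarning):
    """k exceeded the number of distinct colors; extra clusters are empty."""
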