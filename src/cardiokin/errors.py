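"""Exception and warning types shared across the package."""


class CardiokinError(Exception):
    """Base class for all package errors."""


class FormatError(CardiokinError):
    """Unreadable or unsupported video container."""


class InconsistentSequenceError(CardiokinError):
    """Frames in a sequence do not share one shape."""


class InsufficientDataError(CardiokinError):
    """Fewer than two frames, or otherwise too little data to analyse."""


class InvalidProtocolError(CardiokinError):
    """Waveform parameters violate 1:1 capture at the requested pacing rate."""


class RenderError(CardiokinError):
    """Synthetic geometry does not fit inside the frame at maximal excursion."""


class PlacementError(CardiokinError):
    """Marker coordinates fall outside the frame."""


class LostTrackError(CardiokinError):
    """Marker correlation stayed below the floor for too many consecutive frames."""

    def __init__(self, frame: int, score: float):
        self.frame = frame
        self.score = score
        super().__init__(
            f"marker lost at frame {frame} (correlation {score:.3f} below floor)"
        )


class MissingAnchorError(CardiokinError):
    """A beat lacks a distinct contraction or relaxation speed peak."""


class EmptySummaryError(CardiokinError):
    """summarize_beats called with no beats."""


class PairingError(CardiokinError):
    """Comparison inputs do not share matching (tracker, frequency, parameter) keys."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"unmatched comparison keys: {self.missing}")


class UndefinedRatioError(CardiokinError):
    """Frequency ratio requested against a zero base mean."""


class ClassMissingError(CardiokinError):
    """A dataset operation requires both classes to be present."""


class StratificationError(CardiokinError):
    """Too few rows in a class to stratify the train/test split."""


class TrainingError(CardiokinError):
    """Degenerate (single-class) training set."""


class LowConfidenceWarning(UserWarning):
    """Motion estimate produced on featureless or low-texture input."""
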