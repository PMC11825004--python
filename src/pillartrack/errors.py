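"""Exception hierarchy for the analysis pipeline.

Detection failures carry enough context (frame index, half) to be logged
per frame by the tracker and per video by the batch runner.
"""


class PillarTrackError(Exception):
    """Base class for all package errors."""


class ConfigError(PillarTrackError):
    """Invalid platform, preprocessing or run configuration."""


class MediaError(PillarTrackError, OSError):
    """Unreadable or unwritable media file; message names the path."""


class InsufficientFramesError(MediaError):
    """A video decoded to fewer than two frames."""


class UnsupportedFormatError(MediaError):
    """Requested container format is a documented non-goal (e.g. .nd2)."""


class DegenerateHistogramError(PillarTrackError):
    """Constant frame: Otsu's criterion is undefined; manual override needed."""


class DetectionError(PillarTrackError):
    """Per-frame segmentation failure."""

    def __init__(self, message: str, frame_index: int | None = None,
                 half: str | None = None):
        where = []
        if half is not None:
            where.append(f"half={half}")
        if frame_index is not None:
            where.append(f"frame={frame_index}")
        if where:
            message = f"{message} ({', '.join(where)})"
        super().__init__(message)
        self.frame_index = frame_index
        self.half = half


class PillarNotFoundError(DetectionError):
    """No bright contour within the admissible area band of the expected tip."""


class VShapeMaskingError(DetectionError):
    """Sliding-rectangle overlap never reached half the expected tip area."""


class TissueNotFoundError(DetectionError):
    """No dark connected component large enough to be the tissue."""


class TrackingUnreliableError(PillarTrackError):
    """More than the tolerated fraction of frames failed detection."""

    def __init__(self, message: str, failed_frames: list[int] | None = None):
        super().__init__(message)
        self.failed_frames = failed_frames or []


class NoCompleteCycleError(PillarTrackError):
    """The trace contains no peak bounded by minima on both sides."""
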