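"""Frame-by-frame assembly of detection results into time series.

Each pillar is detected independently in every frame (no template
matching or optical flow), so tracking is robust to slow drift and does
not require the tissue to sit symmetrically in the field of view.  The
per-frame inter-centroid Euclidean distance, converted to µm, is the
raw contraction signal; deflection is its drop below the diastolic
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PlatformConfig, PreprocessSettings
from .errors import PillarTrackError, TrackingUnreliableError
from .io_media import FrameStack
from .preprocess import preprocess_frame
from .segmentation import DetectionResult, segment_frame

__all__ = ["TraceSet", "track"]

#: maximum tolerated fraction of frames with failed detection
MAX_FAILED_FRACTION = 0.05
#: longest run of consecutive failed frames that may be interpolated
MAX_GAP = 3


@dataclass
class TraceSet:
    """Per-frame time series of one recording.

    ``deflection_um`` is the *total* gap change (baseline minus current
    inter-centroid distance); the per-pillar bending used for force is
    half of it.  ``baseline_distance_um`` is the diastolic reference:
    the median of the upper decile of the distance series, an order
    statistic robust to noise and to recordings that never fully relax
    while sitting close enough to true diastole that deflection stays
    non-negative up to noise.
    """
    t: np.ndarray
    distance_px: np.ndarray
    distance_um: np.ndarray
    deflection_um: np.ndarray
    tissue_area_px2: np.ndarray
    tissue_area_um2: np.ndarray
    baseline_distance_um: float
    fps: float
    um_per_px: float
    centroids: np.ndarray = field(repr=False)   # (n_frames, 2 pillars, 2)
    failed_frames: list[int] = field(default_factory=list)
    first_detection: DetectionResult | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.t.size


def _interpolate_gaps(series: np.ndarray, failed: list[int]) -> None:
    """Linearly fill NaN runs in place (endpoints extend nearest valid)."""
    bad = np.isnan(series)
    if not bad.any():
        return
    idx = np.arange(series.size)
    series[bad] = np.interp(idx[bad], idx[~bad], series[~bad])


def track(stack: FrameStack,
          config: PlatformConfig,
          settings: PreprocessSettings | None = None,
          manual_threshold: float | None = None) -> TraceSet:
    """Run the full detection pipeline over every frame of a stack.

    Frames where detection fails are linearly interpolated from their
    neighbours, but only up to :data:`MAX_GAP` consecutive frames and
    at most :data:`MAX_FAILED_FRACTION` of the recording; beyond either
    limit a :class:`TrackingUnreliableError` carries the per-frame
    failure list.
    """
    if settings is None:
        settings = PreprocessSettings()
    n = len(stack)
    distance_px = np.full(n, np.nan)
    area_px2 = np.full(n, np.nan)
    centroids = np.full((n, 2, 2), np.nan)
    failed: list[int] = []
    failure_log: list[str] = []
    first_detection: DetectionResult | None = None

    for i, frame in enumerate(stack.frames):
        try:
            pre = preprocess_frame(frame, settings)
            det = segment_frame(pre, config, manual_threshold=manual_threshold,
                                frame_index=i)
        except PillarTrackError as exc:
            failed.append(i)
            failure_log.append(f"frame {i}: {exc}")
            continue
        (r0, c0), (r1, c1) = det.pillars[0].centroid, det.pillars[1].centroid
        centroids[i, 0] = (r0, c0)
        centroids[i, 1] = (r1, c1)
        distance_px[i] = float(np.hypot(r1 - r0, c1 - c0))
        area_px2[i] = det.tissue.area_px2
        if first_detection is None:
            first_detection = det

    if len(failed) > MAX_FAILED_FRACTION * n or first_detection is None:
        raise TrackingUnreliableError(
            f"tracking unreliable: {len(failed)}/{n} frames failed "
            f"detection:\n" + "\n".join(failure_log), failed_frames=failed)
    if failed:
        runs = np.split(np.asarray(failed),
                        np.nonzero(np.diff(failed) > 1)[0] + 1)
        longest = max(len(r) for r in runs)
        if longest > MAX_GAP:
            raise TrackingUnreliableError(
                f"{longest} consecutive frames failed detection "
                f"(max {MAX_GAP} may be interpolated)", failed_frames=failed)
        _interpolate_gaps(distance_px, failed)
        _interpolate_gaps(area_px2, failed)
        for p in range(2):
            for d in range(2):
                _interpolate_gaps(centroids[:, p, d], failed)

    distance_um = distance_px * config.um_per_px
    upper = distance_um >= np.quantile(distance_um, 0.90)
    baseline = float(np.median(distance_um[upper]))
    return TraceSet(
        t=np.arange(n) / stack.fps,
        distance_px=distance_px,
        distance_um=distance_um,
        deflection_um=baseline - distance_um,
        tissue_area_px2=area_px2,
        tissue_area_um2=area_px2 * config.um_per_px ** 2,
        baseline_distance_um=baseline,
        fps=stack.fps,
        um_per_px=config.um_per_px,
        centroids=centroids,
        failed_frames=failed,
        first_detection=first_detection,
    )
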