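"""Otsu binarization and per-half pillar-tip / tissue extraction.

In brightfield, the transparent elastomer pillar tips image bright and
the compacted tissue around them images dark, so a single global Otsu
threshold separates the two classes.  The frame is then split
vertically into two halves — one pillar each — and in every half the
bright connected component whose area best matches the expected tip
area (from the platform geometry) is taken as the pillar.  Centroids
come from the raw image moments of that component, which is what makes
the tracking subpixel even though the mask is binary.

For rectangular pillars a bright cell-free wedge (the "V-shape") is
often fused to the tip's inner face; :func:`mask_v_shape` removes it by
sliding a rectangle of the expected tip size over the component and
keeping the placement with maximum overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from shapely.geometry import MultiPoint

from .config import PlatformConfig
from .errors import (ConfigError, DegenerateHistogramError,
                     PillarNotFoundError, PillarTrackError,
                     TissueNotFoundError, VShapeMaskingError)

__all__ = [
    "BinaryFrame", "PillarShape", "TissueRegion", "DetectionResult",
    "otsu_threshold", "binarize", "split_halves", "detect_pillar",
    "mask_v_shape", "extract_tissue", "segment_frame", "moment_centroid",
]

_EIGHT = np.ones((3, 3), dtype=bool)

#: admissibility band for nearest-area pillar selection
AREA_BAND = 3.0


@dataclass
class BinaryFrame:
    """Binarized frame: True = bright (pillar / background) pixels."""
    mask: np.ndarray
    threshold_used: float
    manual_override: bool = False


@dataclass
class PillarShape:
    """One detected pillar tip.

    ``centroid`` is the raw-moment centroid of the detected component
    (0-based (row, col), subpixel), *not* of the fitted approximation.
    ``params`` holds ``{"radius": r}`` for circles or
    ``{"width": w, "height": h, "rotation_deg": phi}`` for rectangles.
    ``mask`` is the retained component in the coordinate frame the
    detection ran in (a half-frame; offset applied by the caller).
    """
    kind: str
    centroid: tuple[float, float]
    params: dict
    contour_area: float
    mask: np.ndarray | None = field(default=None, repr=False)

    def raster(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the fitted approximation onto a full-frame grid."""
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        r0, c0 = self.centroid
        if self.kind == "circle":
            return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.params["radius"] ** 2
        phi = math.radians(self.params["rotation_deg"])
        dr, dc = rr - r0, cc - c0
        u = dc * math.cos(phi) + dr * math.sin(phi)
        v = -dc * math.sin(phi) + dr * math.cos(phi)
        return ((np.abs(u) <= self.params["width"] / 2)
                & (np.abs(v) <= self.params["height"] / 2))


@dataclass
class TissueRegion:
    """Largest dark connected component, pillar area excluded."""
    mask: np.ndarray = field(repr=False)
    area_px2: float
    area_um2: float


@dataclass
class DetectionResult:
    """Per-frame segmentation output: two pillars plus the tissue."""
    pillars: tuple[PillarShape, PillarShape]
    tissue: TissueRegion
    binary: BinaryFrame


# ----------------------------------------------------------------- Otsu

def otsu_threshold(frame: np.ndarray, nbins: int = 256) -> int:
    """Between-class-variance-maximizing threshold of an 8-bit frame.

    Returns the smallest integer ``t`` maximizing the between-class
    variance of the split ``{<= t} / {> t}`` over a 256-bin histogram.
    Raises :class:`DegenerateHistogramError` on constant frames, where
    the criterion is undefined.
    """
    frame = np.asarray(frame)
    hist = np.bincount(frame.reshape(-1).astype(np.int64),
                       minlength=nbins).astype(np.float64)
    if hist.size > nbins:
        raise PillarTrackError(
            f"intensity {hist.size - 1} exceeds the {nbins}-bin histogram; "
            "rescale the source to 8-bit first")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "constant frame: Otsu threshold undefined (use a manual override)")
    levels = np.arange(nbins, dtype=np.float64)
    w0 = np.cumsum(hist)
    mu0 = np.cumsum(hist * levels)
    w1 = w0[-1] - w0
    mu_total = mu0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu0 / w0
        m1 = (mu_total - mu0) / w1
        sigma_b = w0 * w1 * (m0 - m1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    # argmax returns the first (smallest) maximizing t
    return int(np.argmax(sigma_b))


def binarize(frame: np.ndarray, threshold: float | None = None) -> BinaryFrame:
    """Threshold a frame; bright pixels (> t) become True.

    ``threshold=None`` computes Otsu automatically; a supplied value is
    a manual override and recorded as such.
    """
    manual = threshold is not None
    t = float(threshold) if manual else float(otsu_threshold(frame))
    return BinaryFrame(mask=np.asarray(frame) > t, threshold_used=t,
                       manual_override=manual)


# ------------------------------------------------------------- geometry

def split_halves(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split columns into [0, W//2) and [W//2, W); no pixel lost."""
    frame = np.asarray(frame)
    w = frame.shape[1]
    if w < 4:
        raise PillarTrackError(f"frame width {w} too small to split")
    mid = w // 2
    return frame[:, :mid], frame[:, mid:]


def moment_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Zeroth/first image moments of a binary mask -> (row, col)."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise PillarTrackError("empty mask has no centroid")
    return float(rows.mean()), float(cols.mean())


def _min_area_rect(mask: np.ndarray) -> dict:
    """Minimum-area rotated bounding rectangle of a component mask.

    Side lengths are pixel extents (+1 px on the pixel-center hull),
    ``width >= height``, rotation in degrees of the width edge against
    the column axis, in (-90, 90].
    """
    rows, cols = np.nonzero(mask)
    pts = MultiPoint(list(zip(cols.tolist(), rows.tolist())))
    mrr = pts.minimum_rotated_rectangle
    if mrr.geom_type != "Polygon":  # degenerate: line or point
        minx, miny, maxx, maxy = pts.bounds
        return {"width": maxx - minx + 1, "height": maxy - miny + 1,
                "rotation_deg": 0.0}
    xy = np.asarray(mrr.exterior.coords)[:4]
    e1 = xy[1] - xy[0]
    e2 = xy[2] - xy[1]
    l1, l2 = np.hypot(*e1), np.hypot(*e2)
    if l1 >= l2:
        w, h, edge = l1, l2, e1
    else:
        w, h, edge = l2, l1, e2
    phi = math.degrees(math.atan2(edge[1], edge[0]))
    if phi <= -90:
        phi += 180
    elif phi > 90:
        phi -= 180
    return {"width": w + 1, "height": h + 1, "rotation_deg": phi}


def mask_v_shape(component: np.ndarray,
                 expected_dims_px: tuple[float, float]) -> np.ndarray:
    """Strip the cell-free bright wedge fused to a rectangular tip.

    Exhaustively slides an axis-aligned rectangle of the expected tip
    dimensions (rows, cols) over the component and keeps the integer
    placement with maximum overlap; component pixels outside that
    placement are cleared, so the retained area never exceeds the
    original.  Raises :class:`VShapeMaskingError` when the best overlap
    is below half the expected tip area.
    """
    component = np.asarray(component, dtype=bool)
    hh = max(1, int(round(expected_dims_px[0])))
    ww = max(1, int(round(expected_dims_px[1])))
    rows, cols = np.nonzero(component)
    if rows.size == 0:
        raise VShapeMaskingError("empty component")
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    # pad so placements may extend past the component's bounding box
    sub = component[r0:r1 + 1, c0:c1 + 1]
    pad = np.zeros((sub.shape[0] + 2 * (hh - 1), sub.shape[1] + 2 * (ww - 1)),
                   dtype=np.int64)
    pad[hh - 1:hh - 1 + sub.shape[0], ww - 1:ww - 1 + sub.shape[1]] = sub
    # sliding-window sums via 2-D cumulative sums
    cs = pad.cumsum(0).cumsum(1)
    cs = np.pad(cs, ((1, 0), (1, 0)))
    win = (cs[hh:, ww:] - cs[:-hh, ww:] - cs[hh:, :-ww] + cs[:-hh, :-ww])
    best = np.unravel_index(np.argmax(win), win.shape)  # first = smallest r,c
    if win[best] < 0.5 * hh * ww:
        raise VShapeMaskingError(
            f"best tip overlap {win[best]} px2 is below half the expected "
            f"{hh}x{ww} tip area")
    out = np.zeros_like(component)
    rr = r0 - (hh - 1) + best[0]
    cc = c0 - (ww - 1) + best[1]
    rs, cs_ = max(rr, 0), max(cc, 0)
    re, ce = min(rr + hh, component.shape[0]), min(cc + ww, component.shape[1])
    out[rs:re, cs_:ce] = component[rs:re, cs_:ce]
    return out


def detect_pillar(half_mask: np.ndarray, config: PlatformConfig,
                  frame_index: int | None = None,
                  half: str | None = None) -> PillarShape:
    """Find the pillar tip in one binary half-frame.

    Dimension sorting: among all bright connected components, the one
    whose area is nearest the expected tip area (within a x3 / /3
    admissibility band) is the pillar.  Rectangular platforms get the
    V-shape masking applied before moments are taken.
    """
    half_mask = np.asarray(half_mask, dtype=bool)
    expected = config.expected_tip_area_px2()
    if expected <= 0:
        raise ConfigError("expected pillar-tip area must be positive")
    labels, n = ndi.label(half_mask, structure=_EIGHT)
    if n == 0:
        raise PillarNotFoundError("no bright component in half-frame",
                                  frame_index=frame_index, half=half)
    areas = ndi.sum_labels(half_mask, labels, index=np.arange(1, n + 1))
    admissible = np.nonzero((areas >= expected / AREA_BAND)
                            & (areas <= expected * AREA_BAND))[0]
    if admissible.size == 0:
        raise PillarNotFoundError(
            f"no bright component within x/{AREA_BAND:g} of expected tip "
            f"area {expected:.0f} px2 (component areas: "
            f"{np.sort(areas)[::-1][:4].astype(int).tolist()}...)",
            frame_index=frame_index, half=half)
    pick = admissible[np.argmin(np.abs(areas[admissible] - expected))]
    component = labels == pick + 1

    if config.pillar_kind == "rectangle":
        try:
            component = mask_v_shape(component, config.tip_dims_px())
        except VShapeMaskingError as exc:
            raise VShapeMaskingError(str(exc), frame_index=frame_index,
                                     half=half) from exc

    area = float(component.sum())
    centroid = moment_centroid(component)
    if config.pillar_kind == "circle":
        params = {"radius": math.sqrt(area / math.pi)}
    else:
        params = _min_area_rect(component)
    return PillarShape(kind=config.pillar_kind, centroid=centroid,
                       params=params, contour_area=area, mask=component)


def extract_tissue(binary: BinaryFrame,
                   pillars: tuple[PillarShape, PillarShape],
                   config: PlatformConfig,
                   frame_index: int | None = None) -> TissueRegion:
    """Measure the tissue as the largest dark connected component.

    Pixels the dark component shares with either pillar's fitted shape
    are subtracted, mirroring how manual reference measurements exclude
    the pillar area from the tissue outline.
    """
    dark = ~binary.mask
    labels, n = ndi.label(dark)
    if n == 0:
        raise TissueNotFoundError("no dark pixels in frame",
                                  frame_index=frame_index)
    areas = ndi.sum_labels(dark, labels, index=np.arange(1, n + 1))
    pick = int(np.argmax(areas))
    expected_tip = config.expected_tip_area_px2()
    if areas[pick] < 10 * expected_tip:
        raise TissueNotFoundError(
            f"largest dark component ({areas[pick]:.0f} px2) is below 10x "
            f"the expected pillar-tip area ({expected_tip:.0f} px2)",
            frame_index=frame_index)
    mask = labels == pick + 1
    overlap = 0
    for p in pillars:
        overlap += int(np.count_nonzero(mask & p.raster(mask.shape)))
    area_px2 = float(mask.sum() - overlap)
    return TissueRegion(mask=mask, area_px2=area_px2,
                        area_um2=area_px2 * config.um_per_px ** 2)


def segment_frame(frame: np.ndarray, config: PlatformConfig,
                  manual_threshold: float | None = None,
                  frame_index: int | None = None) -> DetectionResult:
    """Binarize one preprocessed frame and extract pillars + tissue.

    Pillar centroids are returned in full-frame coordinates (the right
    half's column offset is restored).
    """
    binary = binarize(frame, threshold=manual_threshold)
    left, right = split_halves(binary.mask)
    p_left = detect_pillar(left, config, frame_index=frame_index, half="left")
    p_right = detect_pillar(right, config, frame_index=frame_index,
                            half="right")
    mid = frame.shape[1] // 2
    p_right.centroid = (p_right.centroid[0], p_right.centroid[1] + mid)
    if p_right.mask is not None:
        full = np.zeros(binary.mask.shape, dtype=bool)
        full[:, mid:] = p_right.mask
        p_right.mask = full
    if p_left.mask is not None:
        full = np.zeros(binary.mask.shape, dtype=bool)
        full[:, :mid] = p_left.mask
        p_left.mask = full
    tissue = extract_tissue(binary, (p_left, p_right), config,
                            frame_index=frame_index)
    return DetectionResult(pillars=(p_left, p_right), tissue=tissue,
                           binary=binary)
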