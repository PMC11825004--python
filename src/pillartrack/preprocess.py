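"""Pre-thresholding clean-up of brightfield frames.

The chain is fixed: luminosity grayscale conversion, edge-preserving
bilateral smoothing, then a morphological opening (paired erosion and
dilation rounds).  The opening removes small bright artifacts — dust,
cell debris, glitches — without shifting the pillar-tip edges the later
centroid computation depends on.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from skimage.restoration import denoise_bilateral

from .config import PreprocessSettings
from .errors import PillarTrackError

__all__ = ["to_grayscale", "bilateral_smooth", "morph_clean",
           "preprocess_frame"]

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Reduce a frame to a single luminosity channel.

    Already-gray input is returned unchanged; 3-channel input is
    combined with the standard luma weighting.  Integer dtypes are
    preserved (rounded), so an all-channels-equal color frame maps to
    the identical gray values.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] == 3:
        gray = frame.astype(np.float64) @ _LUMA
        if np.issubdtype(frame.dtype, np.integer):
            info = np.iinfo(frame.dtype)
            return np.clip(np.rint(gray), info.min, info.max).astype(frame.dtype)
        return gray
    raise PillarTrackError(
        f"unsupported channel layout: expected 2-D or (H, W, 3), "
        f"got shape {frame.shape}")


def bilateral_smooth(frame: np.ndarray,
                     settings: PreprocessSettings | None = None) -> np.ndarray:
    """Edge-preserving denoising of a grayscale frame.

    Pixels are averaged over a ``bilateral_diameter`` window, weighting
    neighbours both by spatial distance (``bilateral_sigma_space``) and
    by intensity difference (``bilateral_sigma_color``, on the 8-bit
    scale), so step edges between tissue and pillar survive while
    shot-noise is suppressed.  Output dtype and intensity range match
    the input.
    """
    if settings is None:
        settings = PreprocessSettings()
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise PillarTrackError("bilateral_smooth expects a grayscale frame")
    if np.issubdtype(frame.dtype, np.integer):
        scale = float(np.iinfo(frame.dtype).max)
    else:
        scale = 255.0
    f = frame.astype(np.float64) / scale
    out = denoise_bilateral(
        f,
        win_size=settings.bilateral_diameter,
        sigma_color=settings.bilateral_sigma_color / 255.0,
        sigma_spatial=settings.bilateral_sigma_space,
        mode="edge",
    )
    # a weighted average cannot leave the input range; clip guards rounding
    out = np.clip(out, f.min(), f.max()) * scale
    if np.issubdtype(frame.dtype, np.integer):
        return np.rint(out).astype(frame.dtype)
    return out


def _footprint(size: int) -> np.ndarray:
    return np.ones((size, size), dtype=bool)


def morph_clean(frame: np.ndarray,
                settings: PreprocessSettings | None = None) -> np.ndarray:
    """Morphological opening: n erosion rounds then n dilation rounds.

    Works on grayscale (min/max filters) or boolean frames with a
    square structuring element.  Objects that do not survive the
    erosion rounds are removed for good; everything else regains its
    original extent.  ``morph_iterations == 0`` is the identity.
    """
    if settings is None:
        settings = PreprocessSettings()
    n = settings.morph_iterations
    if n == 0:
        return frame
    frame = np.asarray(frame)
    fp = _footprint(settings.morph_kernel)
    if frame.dtype == bool:
        out = ndi.binary_erosion(frame, structure=fp, iterations=n)
        return ndi.binary_dilation(out, structure=fp, iterations=n)
    out = frame
    for _ in range(n):
        out = ndi.grey_erosion(out, footprint=fp)
    for _ in range(n):
        out = ndi.grey_dilation(out, footprint=fp)
    return out


def preprocess_frame(frame: np.ndarray,
                     settings: PreprocessSettings | None = None) -> np.ndarray:
    """Full clean-up chain: grayscale -> bilateral -> opening."""
    if settings is None:
        settings = PreprocessSettings()
    return morph_clean(bilateral_smooth(to_grayscale(frame), settings),
                       settings)
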