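"""Platform and preprocessing configuration.

``PlatformConfig`` holds everything needed to turn pixels into forces:
the pillar cross-section geometry, the elastic constants of the
cantilever, and the optical calibration (µm/px, frame rate).  It is the
single source of truth consumed by segmentation (expected tip area in
pixels), tracking (unit conversion) and mechanics (stiffness).

Units are fixed package-wide: lengths in µm, Young's modulus in Pa,
forces in µN, areas in µm².
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import yaml

from .errors import ConfigError

__all__ = ["PlatformConfig", "PreprocessSettings", "load_config_file"]


@dataclass(frozen=True)
class PlatformConfig:
    """Geometry, material and optics of a two-pillar tissue platform.

    Parameters
    ----------
    pillar_kind :
        Cross-section of the pillar tips as seen by the camera:
        ``"circle"`` or ``"rectangle"``.
    E :
        Young's modulus of the pillar material, Pa (PDMS is ~1-3 MPa).
    L :
        Pillar length from base to tip, µm.
    a :
        Height along the pillar at which the tissue attaches, µm
        (``0 < a <= L``).
    diameter_um :
        Tip diameter for circular pillars, µm.
    width_um, thickness_um :
        Rectangular tips: in-plane width (perpendicular to the line
        connecting the pillars) and bending thickness (along that
        line), µm.
    gap_design_um :
        Unloaded (tissue-free) inter-pillar tip distance, µm; used for
        the resting-tension estimate.
    um_per_px :
        Optical scale of the recording.
    fps :
        Frame rate of the recording, frames/second.
    deflection_read_at :
        Whether the camera observes the pillar tip (``"tip"``, default,
        bottom-view imaging) or the tissue attachment height
        (``"attachment"``, top-view imaging).
    """

    pillar_kind: Literal["circle", "rectangle"]
    E: float
    L: float
    a: float
    um_per_px: float
    fps: float
    diameter_um: float | None = None
    width_um: float | None = None
    thickness_um: float | None = None
    gap_design_um: float | None = None
    deflection_read_at: Literal["tip", "attachment"] = "tip"

    def __post_init__(self) -> None:
        if self.pillar_kind not in ("circle", "rectangle"):
            raise ConfigError(f"unknown pillar_kind {self.pillar_kind!r}")
        if not (self.E > 0):
            raise ConfigError("Young's modulus E must be positive")
        if not (0 < self.a <= self.L):
            raise ConfigError(
                f"attachment height a={self.a} must satisfy 0 < a <= L={self.L}")
        if not (self.um_per_px > 0):
            raise ConfigError("um_per_px must be positive")
        if not (self.fps > 0):
            raise ConfigError("fps must be positive")
        if self.fps < 70:
            warnings.warn(
                f"frame rate {self.fps:g} fps is below the recommended "
                "minimum of 70 fps; contraction kinetics may be undersampled",
                stacklevel=2)
        if self.pillar_kind == "circle":
            if self.diameter_um is None or self.diameter_um <= 0:
                raise ConfigError("circular pillars need a positive diameter_um")
        else:
            if (self.width_um is None or self.width_um <= 0
                    or self.thickness_um is None or self.thickness_um <= 0):
                raise ConfigError(
                    "rectangular pillars need positive width_um and thickness_um")
        if self.deflection_read_at not in ("tip", "attachment"):
            raise ConfigError(
                f"deflection_read_at must be 'tip' or 'attachment', "
                f"got {self.deflection_read_at!r}")

    # --- derived, pixel-space quantities used by segmentation ---------

    def tip_dims_px(self) -> tuple[float, float]:
        """Expected tip extent in pixels, (height_rows, width_cols).

        For circles both entries equal the diameter.  For rectangles the
        in-plane width spans rows and the bending thickness spans
        columns (the pillars face each other along the column axis).
        """
        if self.pillar_kind == "circle":
            d = self.diameter_um / self.um_per_px
            return (d, d)
        return (self.width_um / self.um_per_px,
                self.thickness_um / self.um_per_px)

    def expected_tip_area_px2(self) -> float:
        """Expected area of one pillar tip in px²."""
        if self.pillar_kind == "circle":
            r = 0.5 * self.diameter_um / self.um_per_px
            return math.pi * r * r
        h, w = self.tip_dims_px()
        return h * w

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PreprocessSettings:
    """Knobs of the pre-thresholding clean-up chain.

    The bilateral filter removes pixel-level noise while keeping the
    pillar/tissue edges sharp; the morphological opening (erosion
    rounds followed by the same number of dilation rounds, 3×3 square
    element) removes artifacts larger than single pixels, e.g. pillar
    shadows.  More than 2 opening rounds distorts the tip shapes, so a
    warning is issued above that.
    """

    bilateral_diameter: int = 9          # window size, px
    bilateral_sigma_color: float = 50.0  # intensity units (8-bit scale)
    bilateral_sigma_space: float = 25.0  # px
    morph_iterations: int = 1
    morph_kernel: int = 3

    def __post_init__(self) -> None:
        if self.morph_iterations < 0:
            raise ConfigError("morph_iterations must be >= 0")
        if self.morph_iterations > 2:
            warnings.warn(
                f"morph_iterations={self.morph_iterations} exceeds the "
                "recommended range 0-2; pillar shapes may be distorted",
                stacklevel=2)
        if self.morph_kernel < 3 or self.morph_kernel % 2 == 0:
            raise ConfigError("morph_kernel must be odd and >= 3")
        if self.bilateral_diameter < 3:
            raise ConfigError("bilateral_diameter must be >= 3")
        if self.bilateral_sigma_color <= 0 or self.bilateral_sigma_space <= 0:
            raise ConfigError("bilateral sigmas must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config_file(path) -> dict:
    """Read a YAML run-configuration file into a plain dict.

    Sections recognised by the batch runner: ``platform`` (PlatformConfig
    fields), ``preprocess`` (PreprocessSettings fields), ``overrides``
    (``otsu_value``, ``morph_iterations``), ``graphs`` (list), ``workers``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} did not parse to a mapping")
    return data
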