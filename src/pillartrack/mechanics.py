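"""Beam mechanics: pillar deflection -> absolute contraction force.

The pillar is modelled as an Euler-Bernoulli cantilever of length L
loaded by a point force where the tissue attaches (height ``a``); the
camera observes the deflection at the tip (or, for top-view platforms,
at the attachment height).  For a tip readout,

    delta_tip = F a^2 (3L - a) / (6 E I)   =>   k = 6 E I / (a^2 (3L - a)),

which reduces to the textbook 3EI/L^3 when the load sits at the free
end.  The second moment of area I is pi D^4/64 for circular tips and
w b^3/12 for rectangular ones, with the thickness b oriented along the
line connecting the pillars (the direction the tissue pulls).

Unit bookkeeping: with E in Pa and lengths in µm, E*I/length^3 carries
Pa*µm = 1e-6 N/m = 1e-6 * (µN/µm), hence the 1e-6 factor in
:func:`pillar_stiffness`; forces come out in µN per µm of deflection.

The measured gap change is shared symmetrically by the two pillars
(each bends half of it toward the other), so F = k * (deflection / 2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import PlatformConfig
from .errors import ConfigError, PillarTrackError
from .tracking import TraceSet

__all__ = ["ForceTrace", "second_moment_of_area", "pillar_stiffness",
           "deflection_to_force", "resting_tension", "force_per_area"]

_PA_UM_TO_UN_PER_UM = 1e-6  # Pa * µm^4 / µm^3 -> µN/µm


@dataclass
class ForceTrace:
    """Force series of one recording, baseline-zeroed by construction.

    ``F_uN`` is already referenced to the diastolic baseline (the
    deflection it is computed from is), so the resting tension is
    reported separately rather than subtracted again.
    """
    F_uN: np.ndarray
    k_uN_per_um: float
    resting_tension_uN: float
    F_per_area: np.ndarray | None = field(default=None, repr=False)


def second_moment_of_area(config: PlatformConfig) -> float:
    """I in µm^4 for the configured cross-section."""
    if config.pillar_kind == "circle":
        return math.pi * config.diameter_um ** 4 / 64.0
    return config.width_um * config.thickness_um ** 3 / 12.0


def pillar_stiffness(config: PlatformConfig) -> float:
    """Effective stiffness k in µN per µm of observed deflection."""
    E, L, a = config.E, config.L, config.a
    if a > L:
        raise ConfigError("attachment height a exceeds pillar length L")
    I = second_moment_of_area(config)
    if config.deflection_read_at == "tip":
        k = 6.0 * E * I / (a * a * (3.0 * L - a))
    else:  # deflection observed at the attachment height itself
        k = 3.0 * E * I / a ** 3
    return k * _PA_UM_TO_UN_PER_UM


def resting_tension(config: PlatformConfig, trace: TraceSet) -> float:
    """Static preload from the unloaded-vs-loaded pillar positions, µN.

    The formed tissue pulls the pillars from their as-fabricated gap
    ``gap_design_um`` to the diastolic baseline; each pillar carries
    half of that closure.  Floored at zero (a baseline wider than the
    design gap is physically unexpected and only warned about).
    """
    if config.gap_design_um is None:
        raise ConfigError("gap_design_um required for resting tension")
    k = pillar_stiffness(config)
    closure = config.gap_design_um - trace.baseline_distance_um
    if closure < 0:
        warnings.warn(
            f"diastolic distance {trace.baseline_distance_um:.1f} um exceeds "
            f"the design gap {config.gap_design_um:.1f} um; resting tension "
            "clamped to 0", stacklevel=2)
        return 0.0
    return k * closure / 2.0


def force_per_area(F_uN: np.ndarray,
                   tissue_area_um2: np.ndarray) -> np.ndarray:
    """Elementwise F / same-frame tissue area, µN/µm².

    Frames with non-positive area yield NaN and are excluded from any
    downstream cycle statistics.
    """
    F_uN = np.asarray(F_uN, dtype=float)
    area = np.asarray(tissue_area_um2, dtype=float)
    valid = area > 0
    if not valid.any():
        raise PillarTrackError("tissue area non-positive on every frame")
    if valid.mean() < 0.95:
        warnings.warn("tissue area missing on more than 5% of frames",
                      stacklevel=2)
    out = np.full_like(F_uN, np.nan)
    out[valid] = F_uN[valid] / area[valid]
    return out


def deflection_to_force(trace: TraceSet, config: PlatformConfig) -> ForceTrace:
    """Convert a deflection trace to absolute force (strictly linear).

    F[t] = k * deflection[t] / 2 under the symmetric two-pillar
    convention.  The resting tension is attached when the design gap is
    known, and the force-per-area series when the tissue area is.
    """
    k = pillar_stiffness(config)
    F = k * trace.deflection_um / 2.0
    preload = (resting_tension(config, trace)
               if config.gap_design_um is not None else 0.0)
    fpa = None
    if np.any(np.asarray(trace.tissue_area_um2) > 0):
        fpa = force_per_area(F, trace.tissue_area_um2)
    return ForceTrace(F_uN=F, k_uN_per_um=k, resting_tension_uN=preload,
                      F_per_area=fpa)
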