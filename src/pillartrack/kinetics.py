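"""Contraction-waveform kinetics.

The raw force (or displacement) trace is low-pass filtered with a
zero-phase IIR filter whose cutoff follows the beating frequency found
by Fourier analysis, then cut into complete contraction cycles — each a
peak bounded by the two local minima around it.  Cycles truncated by
the start or end of the recording are discarded.  Per cycle, the times
to reach 10% and 90% of the amplitude on the upstroke (from the cycle
start) and to decay back to 90% and 10% (from the peak) are located by
linear interpolation between samples, and contraction / relaxation
velocities are the extreme finite-difference slopes within each limb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import NoCompleteCycleError, PillarTrackError

__all__ = ["CycleMetrics", "dominant_frequency", "lowpass",
           "segment_cycles", "cycle_metrics", "analyze_trace",
           "aggregate_metrics", "DEFAULT_CUTOFF_HZ"]

#: fallback low-pass cutoff when no periodic signal is found, Hz
DEFAULT_CUTOFF_HZ = 10.0
#: frequency band searched for the beating peak, Hz
FREQ_BAND = (0.2, 8.0)
#: spectral peak must exceed this multiple of the in-band median
PEAK_OVER_MEDIAN = 3.0
#: peak prominence threshold, fraction of the largest peak amplitude
PROMINENCE_FRACTION = 0.20


@dataclass
class CycleMetrics:
    """Kinetics of one complete contraction cycle.

    Times are in seconds: ``t_up10``/``t_up90`` from the cycle-start
    minimum, ``t_down90``/``t_down10`` from the peak (decay *to* 90%
    and 10% of the amplitude).  Velocities are in signal units per
    second (µN/s on a force trace).
    """
    cycle_start_idx: int
    peak_idx: int
    cycle_end_idx: int
    peak_force_uN: float
    amplitude: float
    t_up10: float
    t_up90: float
    t_down90: float
    t_down10: float
    contraction_velocity: float
    relaxation_velocity: float
    frequency_hz: float | None = None

    @property
    def contraction_time_10_90(self) -> float:
        """Duration of the 10%->90% portion of the upstroke, s."""
        return self.t_up90 - self.t_up10

    @property
    def relaxation_time_90_10(self) -> float:
        """Duration of the 90%->10% portion of the downstroke, s."""
        return self.t_down10 - self.t_down90


def dominant_frequency(x: np.ndarray, fps: float,
                       band: tuple[float, float] = FREQ_BAND) -> float | None:
    """Beating frequency from the largest non-DC spectral peak, Hz.

    Returns ``None`` (with a warning) when no in-band peak rises at
    least :data:`PEAK_OVER_MEDIAN` times above the in-band spectral
    median — e.g. on white noise — in which case filtering falls back
    to :data:`DEFAULT_CUTOFF_HZ`.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * fps:
        raise PillarTrackError("need at least 2 s of data for the spectrum")
    spec = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fps)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise PillarTrackError("search band empty at this fps/duration")
    i = np.argmax(spec[sel])
    peak, med = spec[sel][i], np.median(spec[sel])
    if med > 0 and peak < PEAK_OVER_MEDIAN * med:
        warnings.warn("no periodic signal found in band; low-pass falls "
                      f"back to {DEFAULT_CUTOFF_HZ:g} Hz", stacklevel=2)
        return None
    # parabolic interpolation around the peak bin for sub-bin resolution
    j = np.nonzero(sel)[0][i]
    if 0 < j < spec.size - 1:
        y0, y1, y2 = spec[j - 1:j + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            shift = np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)
            return float((j + shift) * fps / x.size)
    return float(freqs[j])


def lowpass(x: np.ndarray, f0: float | None, fps: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass.

    Cutoff = min(10 * f0, 0.8 * Nyquist); the factor 10 keeps the first
    harmonics of the contraction waveform (hence its T10/T90 timing)
    intact while stripping broadband noise.  Forward-backward filtering
    introduces no phase delay.
    """
    x = np.asarray(x, dtype=float)
    if f0 is None:
        f0 = DEFAULT_CUTOFF_HZ / 10.0
    cutoff = min(10.0 * f0, 0.8 * fps / 2.0)
    if not (0 < cutoff < fps / 2.0):
        raise PillarTrackError(
            f"infeasible low-pass cutoff {cutoff:g} Hz at {fps:g} fps")
    sos = signal.butter(4, cutoff, btype="low", fs=fps, output="sos")
    return signal.sosfiltfilt(sos, x)


def _is_local_min(x: np.ndarray, i: int) -> bool:
    return 0 < i < x.size - 1 and x[i] <= x[i - 1] and x[i] <= x[i + 1]


def segment_cycles(x: np.ndarray) -> list[tuple[int, int, int]]:
    """Split a filtered trace into complete (start, peak, end) cycles.

    Peaks are local maxima with prominence of at least
    :data:`PROMINENCE_FRACTION` of the largest peak amplitude; each is
    paired with the minima on either side (the argmin of the trace
    between neighbouring peaks, shared by adjacent cycles).  Peaks whose
    flanking minimum falls on a recording endpoint — a cycle the video
    cut into — are discarded.
    """
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span <= 0:
        raise NoCompleteCycleError("constant trace has no cycles")
    peaks, _ = signal.find_peaks(x, prominence=PROMINENCE_FRACTION * span)
    if peaks.size == 0:
        raise NoCompleteCycleError("no peaks above the prominence threshold")
    cycles = []
    for j, p in enumerate(peaks):
        lo = peaks[j - 1] if j > 0 else 0
        hi = peaks[j + 1] if j + 1 < peaks.size else x.size - 1
        start = lo + int(np.argmin(x[lo:p + 1]))
        end = p + int(np.argmin(x[p:hi + 1]))
        if not (_is_local_min(x, start) and _is_local_min(x, end)):
            continue  # truncated by recording start/end
        cycles.append((start, p, end))
    if not cycles:
        raise NoCompleteCycleError("no peak bounded by minima on both sides")
    return cycles


def _cross_time(x: np.ndarray, i0: int, i1: int, level: float,
                fps: float, rising: bool) -> float | None:
    """First linearly interpolated crossing of ``level`` in [i0, i1]."""
    seg = x[i0:i1 + 1]
    if rising:
        hit = np.nonzero(seg >= level)[0]
    else:
        hit = np.nonzero(seg <= level)[0]
    if hit.size == 0:
        return None
    i = hit[0]
    if i == 0:
        return 0.0
    frac = (level - seg[i - 1]) / (seg[i] - seg[i - 1])
    return (i - 1 + float(frac)) / fps


def cycle_metrics(x: np.ndarray, cycle: tuple[int, int, int],
                  fps: float,
                  frequency_hz: float | None = None) -> CycleMetrics | None:
    """Kinetics of one cycle of a filtered trace; None for flat cycles.

    Amplitude is peak minus cycle-start value; threshold levels are
    fractions of it above the start value.  Velocities come from
    central finite differences restricted to the respective limb.
    """
    s, p, e = cycle
    x = np.asarray(x, dtype=float)
    amp = x[p] - x[s]
    if amp <= 0:
        return None
    base = x[s]
    t_up10 = _cross_time(x, s, p, base + 0.1 * amp, fps, rising=True)
    t_up90 = _cross_time(x, s, p, base + 0.9 * amp, fps, rising=True)
    t_dn90 = _cross_time(x, p, e, base + 0.9 * amp, fps, rising=False)
    t_dn10 = _cross_time(x, p, e, base + 0.1 * amp, fps, rising=False)
    if None in (t_up10, t_up90, t_dn90, t_dn10):
        return None
    d = np.gradient(x, 1.0 / fps)
    v_con = float(d[s:p + 1].max())
    v_rel = float(-d[p:e + 1].min())
    return CycleMetrics(
        cycle_start_idx=int(s), peak_idx=int(p), cycle_end_idx=int(e),
        peak_force_uN=float(x[p]), amplitude=float(amp),
        t_up10=t_up10, t_up90=t_up90, t_down90=t_dn90, t_down10=t_dn10,
        contraction_velocity=v_con, relaxation_velocity=v_rel,
        frequency_hz=frequency_hz)


def analyze_trace(x: np.ndarray, fps: float
                  ) -> tuple[np.ndarray, float | None, list[CycleMetrics]]:
    """Filter a raw trace, segment it, and compute all cycle metrics.

    Returns (filtered trace, dominant frequency or None, metrics list).
    Flat cycles are skipped.
    """
    f0 = dominant_frequency(x, fps)
    filt = lowpass(x, f0, fps)
    out = []
    for cyc in segment_cycles(filt):
        m = cycle_metrics(filt, cyc, fps, frequency_hz=f0)
        if m is not None:
            out.append(m)
    return filt, f0, out


def aggregate_metrics(metrics: list[CycleMetrics]) -> dict[str, float]:
    """Per-recording mean and SEM over cycles for every metric."""
    fields = ["peak_force_uN", "amplitude", "t_up10", "t_up90", "t_down90",
              "t_down10", "contraction_time_10_90", "relaxation_time_90_10",
              "contraction_velocity", "relaxation_velocity"]
    out: dict[str, float] = {"n_cycles": float(len(metrics))}
    for name in fields:
        vals = np.array([getattr(m, name) for m in metrics], dtype=float)
        if vals.size:
            out[f"{name}_mean"] = float(vals.mean())
            out[f"{name}_sem"] = (float(vals.std(ddof=1) / np.sqrt(vals.size))
                                  if vals.size > 1 else 0.0)
        else:
            out[f"{name}_mean"] = float("nan")
            out[f"{name}_sem"] = float("nan")
    return out
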