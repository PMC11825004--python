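"""Video ingestion and standard output writing.

Recordings arrive as multi-page TIFF stacks (lossless, the canonical
test surface) or uncompressed AVI; both are normalized to an 8-bit
grayscale :class:`FrameStack`.  Sources with deeper bit depths (11-bit
scientific cameras are common) are rescaled to the 8-bit range so a
single 256-bin Otsu histogram applies everywhere.

Outputs per analyzed video: a per-frame detail table, a per-cycle
metrics table, and a detection snapshot of the first frame with the
fitted contours overlaid.  Per batch: a one-row-per-video summary
table, the selected time-series graphs, and a plain-text log.  Tables
are CSV (diffable, byte-reproducible); ``excel=True`` additionally
emits .xlsx copies of the two main tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile

from . import _avi
from .errors import (InsufficientFramesError, MediaError, PillarTrackError,
                     UnsupportedFormatError)
from .preprocess import to_grayscale
from .results import VideoResult

__all__ = ["FrameStack", "load_video", "save_stack", "write_outputs",
           "GRAPHS"]

GRAPHS = ("displacement", "FoC", "contraction_times", "force_per_area")


@dataclass
class FrameStack:
    """Ordered grayscale frames plus acquisition metadata.

    ``frames`` is a (T, H, W) array; intensities are bounded by
    ``2**bit_depth - 1``.  ``um_per_px`` and ``fps`` come from the
    platform configuration when the container does not carry them.
    """
    frames: np.ndarray
    fps: float
    bit_depth: int = 8
    um_per_px: float = 1.0
    source_path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise PillarTrackError(
                f"FrameStack needs (T, H, W) frames, got {self.frames.shape}")
        if self.fps <= 0:
            raise PillarTrackError("fps must be positive")
        if self.um_per_px <= 0:
            raise PillarTrackError("um_per_px must be positive")
        if (np.issubdtype(self.frames.dtype, np.integer)
                and self.frames.size
                and int(self.frames.max()) > 2 ** self.bit_depth - 1):
            raise PillarTrackError(
                f"intensities exceed the declared {self.bit_depth}-bit depth")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def _rescale_to_8bit(frames: np.ndarray, bit_depth: int) -> np.ndarray:
    if frames.dtype == np.uint8 and bit_depth == 8:
        return frames
    peak = float(2 ** bit_depth - 1)
    return np.clip(np.rint(frames.astype(np.float64) * (255.0 / peak)),
                   0, 255).astype(np.uint8)


def load_video(path, fmt: str | None = None, *, fps: float | None = None,
               um_per_px: float = 1.0,
               source_bit_depth: int | None = None) -> FrameStack:
    """Read an AVI or multi-page TIFF into an 8-bit grayscale stack.

    ``fmt`` defaults to the file suffix.  ``fps`` overrides (or, for
    TIFF, supplies) the frame rate.  ``source_bit_depth`` declares the
    camera depth of >8-bit containers (defaults to the dtype's full
    width); frames are rescaled to 8-bit accordingly.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = {"tiff": "tif"}.get(fmt, fmt)
    if fmt == "nd2":
        raise UnsupportedFormatError(
            f"{path}: .nd2 is a proprietary format and is not supported; "
            "export to TIFF or uncompressed AVI")
    if fmt not in ("avi", "tif"):
        raise UnsupportedFormatError(f"{path}: unknown format {fmt!r}")
    if not path.exists() or path.stat().st_size == 0:
        raise MediaError(f"cannot read video file {path}: missing or empty")

    if fmt == "avi":
        frames, container_fps = _avi.read_avi(path)
        if fps is None:
            fps = container_fps
    else:
        try:
            frames = tifffile.imread(path)
        except Exception as exc:
            raise MediaError(f"cannot read TIFF file {path}: {exc}") from exc
        if fps is None:
            raise MediaError(
                f"{path}: TIFF carries no frame rate; pass fps explicitly")

    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # (T, H, W, C) color
        frames = np.stack([to_grayscale(f) for f in frames])
    if frames.shape[0] < 2:
        raise InsufficientFramesError(
            f"{path}: insufficient frames ({frames.shape[0]}; need >= 2)")

    if source_bit_depth is None:
        source_bit_depth = 8 if frames.dtype == np.uint8 else \
            max(8, int(np.ceil(np.log2(float(frames.max()) + 1))))
    frames = _rescale_to_8bit(frames, source_bit_depth)
    return FrameStack(frames=frames, fps=float(fps), bit_depth=8,
                      um_per_px=um_per_px, source_path=str(path))


def save_stack(stack: FrameStack, path, fmt: str | None = None) -> Path:
    """Write a stack as multi-page TIFF (lossless) or uncompressed AVI."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = {"tiff": "tif"}.get(fmt, fmt)
    if fmt == "tif":
        tifffile.imwrite(path, stack.frames)
    elif fmt == "avi":
        _avi.write_avi(path, stack.frames, stack.fps)
    else:
        raise UnsupportedFormatError(f"cannot write format {fmt!r}")
    return path


# ------------------------------------------------------------- outputs

def _detail_frame(res: VideoResult) -> pd.DataFrame:
    tr = res.traces
    df = pd.DataFrame({
        "frame": np.arange(len(tr)),
        "time_s": tr.t,
        "distance_px": tr.distance_px,
        "distance_um": tr.distance_um,
        "deflection_um": tr.deflection_um,
        "tissue_area_px2": tr.tissue_area_px2,
        "tissue_area_um2": tr.tissue_area_um2,
    })
    if res.force is not None:
        df["force_uN"] = res.force.F_uN
        if res.filtered_force is not None:
            df["force_filtered_uN"] = res.filtered_force
        df["force_per_area_uN_per_um2"] = (
            res.force.F_per_area if res.force.F_per_area is not None
            else np.nan)
    df["detection_failed"] = 0
    df.loc[df["frame"].isin(tr.failed_frames), "detection_failed"] = 1
    return df


def _cycles_frame(res: VideoResult) -> pd.DataFrame:
    rows = []
    for i, m in enumerate(res.cycles):
        rows.append({
            "cycle": i,
            "cycle_start_idx": m.cycle_start_idx,
            "peak_idx": m.peak_idx,
            "cycle_end_idx": m.cycle_end_idx,
            "peak_force_uN": m.peak_force_uN,
            "amplitude_uN": m.amplitude,
            "t_up10_s": m.t_up10,
            "t_up90_s": m.t_up90,
            "t_down90_s": m.t_down90,
            "t_down10_s": m.t_down10,
            "contraction_time_10_90_s": m.contraction_time_10_90,
            "relaxation_time_90_10_s": m.relaxation_time_90_10,
            "contraction_velocity_uN_per_s": m.contraction_velocity,
            "relaxation_velocity_uN_per_s": m.relaxation_velocity,
        })
    return pd.DataFrame(rows)


def _summary_row(res: VideoResult) -> dict:
    row: dict = {
        "file": Path(res.path).name,
        "status": res.status,
        "otsu_override": res.overrides.get("otsu_value", ""),
        "morph_iterations_override": res.overrides.get("morph_iterations", ""),
    }
    if not res.ok:
        row["error"] = res.error
        return row
    tr = res.traces
    row.update({
        "n_frames": len(tr),
        "n_failed_frames": len(tr.failed_frames),
        "frequency_hz": res.frequency_hz,
        "baseline_distance_um": tr.baseline_distance_um,
        "mean_tissue_area_um2": float(np.nanmean(tr.tissue_area_um2)),
        "stiffness_uN_per_um": res.force.k_uN_per_um if res.force else np.nan,
        "resting_tension_uN": (res.force.resting_tension_uN
                               if res.force else np.nan),
    })
    row.update(res.aggregates)
    return row


def _snapshot(res: VideoResult, path: Path) -> None:
    det = res.traces.first_detection
    frame = res.first_frame
    fig, ax = plt.subplots(figsize=(6, 6 * frame.shape[0] / frame.shape[1]))
    ax.imshow(frame, cmap="gray", interpolation="nearest")
    ax.contour(det.tissue.mask, levels=[0.5], colors="orange", linewidths=1)
    for p in det.pillars:
        ax.contour(p.raster(frame.shape), levels=[0.5], colors="cyan",
                   linewidths=1)
        ax.plot(p.centroid[1], p.centroid[0], "+", color="red", ms=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def _batch_plots(results: list[VideoResult], out_dir: Path,
                 graphs: tuple[str, ...]) -> list[Path]:
    ok = [r for r in results if r.ok]
    written: list[Path] = []
    specs = {
        "displacement": ("Pillar displacement", "deflection (um)",
                         lambda r: (r.traces.t, r.traces.deflection_um)),
        "FoC": ("Force of contraction", "force (uN)",
                lambda r: (r.traces.t, r.force.F_uN)),
        "force_per_area": ("Force per tissue surface area", "uN/um^2",
                           lambda r: (r.traces.t, r.force.F_per_area)),
    }
    for name in graphs:
        path = out_dir / f"{name}.png"
        fig, ax = plt.subplots(figsize=(7, 4))
        if name == "contraction_times":
            for r in ok:
                tt = [r.traces.t[m.peak_idx] for m in r.cycles]
                ax.plot(tt, [m.contraction_time_10_90 for m in r.cycles],
                        "o-", label=f"{Path(r.path).stem} TC 10-90%")
                ax.plot(tt, [m.relaxation_time_90_10 for m in r.cycles],
                        "s--", label=f"{Path(r.path).stem} TR 90-10%")
            ax.set_ylabel("time (s)")
            ax.set_title("Contraction / relaxation times per cycle")
        else:
            title, ylab, getter = specs[name]
            for r in ok:
                if name != "displacement" and r.force is None:
                    continue
                t, y = getter(r)
                if y is None:
                    continue
                ax.plot(t, y, lw=1, label=Path(r.path).stem)
            ax.set_ylabel(ylab)
            ax.set_title(title)
        ax.set_xlabel("time (s)")
        if ok:
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written


def write_outputs(results: list[VideoResult], out_dir,
                  graphs: tuple[str, ...] = GRAPHS,
                  excel: bool = False) -> dict:
    """Write every standard output for a batch of analyzed videos.

    Returns a manifest dict of the written paths.  Plotting failures
    are logged but never abort table writing.
    """
    if not results:
        raise PillarTrackError("no results to write")
    bad = set(graphs) - set(GRAPHS)
    if bad:
        raise PillarTrackError(f"unknown graph selection: {sorted(bad)}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise MediaError(f"output directory {out_dir} is not writable: "
                         f"{exc}") from exc

    manifest: dict = {"details": [], "cycles": [], "snapshots": [],
                      "plots": []}
    log_lines: list[str] = []
    for res in sorted(results, key=lambda r: Path(r.path).name):
        stem = Path(res.path).stem
        if res.ok:
            detail = _detail_frame(res)
            p = out_dir / f"{stem}_detail.csv"
            detail.to_csv(p, index=False)
            manifest["details"].append(p)
            if excel:
                detail.to_excel(out_dir / f"{stem}_detail.xlsx", index=False)
            pc = out_dir / f"{stem}_cycles.csv"
            _cycles_frame(res).to_csv(pc, index=False)
            manifest["cycles"].append(pc)
            if res.first_frame is not None:
                ps = out_dir / f"{stem}_detection.png"
                try:
                    _snapshot(res, ps)
                    manifest["snapshots"].append(ps)
                except Exception as exc:     # plotting must not abort tables
                    log_lines.append(f"WARN {stem}: snapshot failed: {exc}")
            log_lines.append(
                f"OK {Path(res.path).name}: {len(res.traces)} frames, "
                f"{len(res.cycles)} cycles, "
                f"{len(res.traces.failed_frames)} interpolated frames")
        else:
            log_lines.append(f"FAILED {Path(res.path).name}: {res.error}")

    summary = pd.DataFrame([_summary_row(r) for r in
                            sorted(results, key=lambda r: Path(r.path).name)])
    summary_path = out_dir / "summary.csv"
    summary.to_csv(summary_path, index=False)
    manifest["summary"] = summary_path
    if excel:
        summary.to_excel(out_dir / "summary.xlsx", index=False)

    try:
        manifest["plots"] = _batch_plots(results, out_dir, graphs)
    except Exception as exc:
        log_lines.append(f"WARN batch plots failed: {exc}")

    log_path = out_dir / "analysis_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    manifest["log"] = log_path
    return manifest
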