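"""Batch orchestration over folders of recordings.

Each video runs the full pipeline — load, track, force conversion,
kinetics — independently; a failure is recorded and logged without
aborting the batch.  Parallelism is process-based (the per-video work
is CPU-bound image processing) and results are merged in filename
order, so output files are byte-identical regardless of worker count.
"""

from __future__ import annotations

import fnmatch
import traceback
import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path

from .config import PlatformConfig, PreprocessSettings, load_config_file
from .errors import ConfigError, PillarTrackError
from .io_media import GRAPHS, load_video, write_outputs
from .kinetics import aggregate_metrics, analyze_trace
from .mechanics import deflection_to_force
from .results import VideoResult
from .tracking import track

__all__ = ["RunConfig", "analyze_video", "run_batch",
           "apply_manual_override"]


@dataclass
class RunConfig:
    """One batch run: where the videos are and how to analyze them."""
    input_dir: Path
    platform: PlatformConfig
    fmt: str = "tif"
    preprocess: PreprocessSettings = field(default_factory=PreprocessSettings)
    overrides: dict = field(default_factory=dict)       # global overrides
    per_file_overrides: dict = field(default_factory=dict)
    graphs: tuple[str, ...] = GRAPHS
    workers: int = 1
    excel: bool = False

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        if not self.input_dir.is_dir():
            raise ConfigError(f"input directory {self.input_dir} not found")
        if self.workers < 1:
            raise ConfigError("worker count must be >= 1")
        bad = set(self.graphs) - set(GRAPHS)
        if bad:
            raise ConfigError(f"unknown graphs {sorted(bad)}; "
                              f"choose from {GRAPHS}")

    @classmethod
    def from_file(cls, path, input_dir=None, **kw) -> "RunConfig":
        """Build from a YAML config file (sections: platform, preprocess,
        overrides, per_file_overrides, graphs, workers, fmt, input_dir)."""
        data = load_config_file(path)
        platform = PlatformConfig(**data["platform"])
        pre = PreprocessSettings(**data.get("preprocess", {}))
        args = dict(
            input_dir=input_dir or data.get("input_dir", "."),
            platform=platform, preprocess=pre,
            fmt=data.get("fmt", "tif"),
            overrides=data.get("overrides", {}) or {},
            per_file_overrides=data.get("per_file_overrides", {}) or {},
            graphs=tuple(data.get("graphs", GRAPHS)),
            workers=int(data.get("workers", 1)),
            excel=bool(data.get("excel", False)),
        )
        args.update(kw)
        return cls(**args)


def apply_manual_override(settings: PreprocessSettings, overrides: dict
                          ) -> tuple[PreprocessSettings, float | None]:
    """Validate manual corrections and fold them into the pipeline.

    Supported keys: ``otsu_value`` (bypasses automatic thresholding)
    and ``morph_iterations``.  Returns the adjusted settings and the
    manual threshold (or None for automatic Otsu).
    """
    unknown = set(overrides) - {"otsu_value", "morph_iterations"}
    if unknown:
        raise ConfigError(f"unknown override keys {sorted(unknown)}")
    otsu = overrides.get("otsu_value")
    if otsu is not None and not (0 <= otsu <= 255):
        raise ConfigError(f"manual Otsu value {otsu} outside the 8-bit "
                          "intensity range")
    if "morph_iterations" in overrides:
        settings = replace(settings,
                           morph_iterations=int(overrides["morph_iterations"]))
    return settings, otsu


def analyze_video(path, platform: PlatformConfig,
                  settings: PreprocessSettings | None = None,
                  overrides: dict | None = None,
                  fmt: str | None = None) -> VideoResult:
    """Full pipeline on one video; failures are captured, not raised."""
    path = Path(path)
    overrides = overrides or {}
    try:
        settings, manual_otsu = apply_manual_override(
            settings or PreprocessSettings(), overrides)
        stack = load_video(path, fmt=fmt, fps=platform.fps,
                           um_per_px=platform.um_per_px)
        traces = track(stack, platform, settings,
                       manual_threshold=manual_otsu)
        force = deflection_to_force(traces, platform)
        freq, cycles, filtered = None, [], None
        try:
            filtered, freq, cycles = analyze_trace(force.F_uN, platform.fps)
        except PillarTrackError as exc:
            warnings.warn(f"{path.name}: kinetics unavailable ({exc})",
                          stacklevel=2)
        return VideoResult(
            path=path, status="ok", traces=traces, force=force,
            filtered_force=filtered, frequency_hz=freq, cycles=cycles,
            aggregates=aggregate_metrics(cycles), overrides=dict(overrides),
            first_frame=stack.frames[0])
    except PillarTrackError as exc:
        return VideoResult(path=path, status="failed", error=str(exc),
                           overrides=dict(overrides))
    except Exception as exc:  # unexpected: keep the batch alive, log fully
        return VideoResult(path=path, status="failed",
                           error=f"{exc}\n{traceback.format_exc()}",
                           overrides=dict(overrides))


def _job(args) -> VideoResult:
    return analyze_video(*args)


def run_batch(config: RunConfig, out_dir=None,
              progress: bool = False) -> tuple[list[VideoResult], dict | None]:
    """Analyze every matching video in the input directory.

    Files are processed in sorted filename order; with ``workers > 1``
    they are distributed over a process pool but merged back in the
    same order, so outputs do not depend on scheduling.  Returns the
    result list and, when ``out_dir`` is given, the written-file
    manifest from :func:`pillartrack.io_media.write_outputs`.
    """
    paths = sorted(config.input_dir.glob(f"*.{config.fmt}"))
    if not paths:
        raise PillarTrackError(
            f"no *.{config.fmt} files in {config.input_dir}")

    def overrides_for(p: Path) -> dict:
        ov = dict(config.overrides)
        for pattern, extra in config.per_file_overrides.items():
            if fnmatch.fnmatch(p.name, pattern):
                ov.update(extra)
        return ov

    jobs = [(p, config.platform, config.preprocess, overrides_for(p),
             config.fmt) for p in paths]
    results: list[VideoResult] = []
    if config.workers == 1:
        for i, job in enumerate(jobs):
            results.append(_job(job))
            if progress:
                print(f"progress: {100 * (i + 1) // len(jobs)}%", flush=True)
    else:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            for i, res in enumerate(pool.map(_job, jobs)):
                results.append(res)
                if progress:
                    print(f"progress: {100 * (i + 1) // len(jobs)}%",
                          flush=True)

    manifest = None
    if out_dir is not None:
        manifest = write_outputs(results, out_dir, graphs=config.graphs,
                                 excel=config.excel)
    return results, manifest
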