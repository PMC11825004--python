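"""Per-video analysis result container shared by io and batch layers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np


@dataclass
class VideoResult:
    """Everything one analyzed video produced (or the reason it failed).

    ``overrides`` records any manual Otsu / morphology settings used,
    for provenance in the output tables.
    """
    path: Path
    status: str                      # "ok" | "failed"
    error: str | None = None
    traces: Any = None               # TraceSet
    force: Any = None                # ForceTrace
    filtered_force: np.ndarray | None = field(default=None, repr=False)
    frequency_hz: float | None = None
    cycles: list = field(default_factory=list)        # list[CycleMetrics]
    aggregates: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)
    first_frame: np.ndarray | None = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.status == "ok"
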