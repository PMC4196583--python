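"""Kymographs and vessel-diameter estimation.

A kymograph reslices a time-lapse stack along a fixed scan line drawn
orthogonal to the vessel axis: each frame contributes one column, so rows
are position along the line and time increases from left to right.  On a
binary-mask kymograph the two wall bands bound the excluded lumen, which
makes per-frame diameter estimation a run-counting problem: the lumen
diameter in a column is the number of excluded pixels strictly between
the inner edges of the two outermost kept runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, median_filter

from .errors import ConfigError, DataError
from .segmentation import BinaryMaskStack
from .stacks import normalize_baseline

log = logging.getLogger(__name__)

__all__ = ["ScanLine", "Kymograph", "reslice", "diameter_trace",
           "DiameterResult"]


@dataclass(frozen=True)
class ScanLine:
    """Scan line from (x0, y0) to (x1, y1), sampled at ~1 px spacing.

    Must be long enough (>= 3 px) and drawn so that it crosses both
    vessel walls in every frame; :func:`diameter_trace` verifies the
    latter at runtime.
    """

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ConfigError("scan line must be at least 3 px long")

    @property
    def length(self) -> float:
        return float(np.hypot(self.x1 - self.x0, self.y1 - self.y0))

    def sample_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of ~unit-spaced sample points along the line."""
        n = int(round(self.length)) + 1
        t = np.linspace(0.0, 1.0, n)
        cols = self.x0 + t * (self.x1 - self.x0)
        rows = self.y0 + t * (self.y1 - self.y0)
        return rows, cols

    @classmethod
    def parse(cls, text: str) -> "ScanLine":
        """Parse 'x0,y0,x1,y1' (the CLI --line format)."""
        parts = [float(p) for p in text.split(",")]
        if len(parts) != 4:
            raise ConfigError("scan line must be 'x0,y0,x1,y1'")
        return cls(*parts)


@dataclass
class Kymograph:
    """Space-time image: rows = position along the line, cols = time."""

    data: np.ndarray
    source: str = "intensity"        # mask | intensity | ratio
    line: ScanLine | None = None
    frame_interval: float = 5.0

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def reslice(stack_or_mask, line: ScanLine, interpolation: str | None = None,
            frame_interval: float | None = None) -> Kymograph:
    """Sample every frame along the scan line into one kymograph column.

    Masks are sampled nearest-neighbor (so kept/excluded states are never
    blended); intensity and ratio stacks default to nearest but support
    ``interpolation='bilinear'``.
    """
    if isinstance(stack_or_mask, BinaryMaskStack):
        arr = stack_or_mask.keep.astype(float)
        source, order = "mask", 0
        if interpolation == "bilinear":
            raise ConfigError("mask kymographs must use nearest-neighbor")
    else:
        arr = np.asarray(getattr(stack_or_mask, "donor", stack_or_mask),
                         dtype=float)
        source = "intensity"
        order = 1 if interpolation == "bilinear" else 0
        if hasattr(stack_or_mask, "frame_interval") and frame_interval is None:
            frame_interval = stack_or_mask.frame_interval
    if arr.ndim != 3:
        raise DataError("expected a (frames, height, width) stack")
    rows, cols = line.sample_points()
    h, w = arr.shape[1:]
    if (rows.min() < -0.5 or rows.max() > h - 0.5
            or cols.min() < -0.5 or cols.max() > w - 0.5):
        raise ConfigError("scan line exits the image")
    columns = np.empty((rows.size, arr.shape[0]))
    for i in range(arr.shape[0]):
        frame = arr[i]
        if order == 1 and not np.all(np.isfinite(frame)):
            # bilinear would smear NaN; sample finite values nearest instead
            columns[:, i] = map_coordinates(frame, [rows, cols], order=0,
                                            mode="nearest")
        else:
            columns[:, i] = map_coordinates(frame, [rows, cols], order=order,
                                            mode="nearest")
    return Kymograph(columns, source=source, line=line,
                     frame_interval=frame_interval or 5.0)


@dataclass
class DiameterResult:
    """Per-frame diameter estimate and normalized change."""

    diameter_px: np.ndarray
    dd_d: np.ndarray
    flagged_columns: np.ndarray
    edges: np.ndarray          # (n_frames, 2): inner edge rows (lo, hi)


def _column_runs(col: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Start/stop (inclusive) of kept runs of length >= min_run."""
    kept = col > 0.5
    if not kept.any():
        return []
    d = np.diff(kept.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0])
    if kept[0]:
        starts.insert(0, 0)
    if kept[-1]:
        stops.append(len(kept) - 1)
    return [(a, b) for a, b in zip(starts, stops) if b - a + 1 >= min_run]


def diameter_trace(kymo: Kymograph, baseline_frames, min_run: int = 2,
                   measure: str = "lumen", max_flagged_fraction: float = 0.10,
                   median_width: int = 1) -> DiameterResult:
    """Estimate vessel diameter per frame from a mask kymograph.

    Per column, speckle runs shorter than ``min_run`` are discarded and
    the two outermost remaining kept runs are taken as the walls.  The
    default ``lumen`` measure counts the excluded pixels strictly between
    the walls' inner edges; ``outer`` spans outer edge to outer edge.
    Columns with fewer than two wall runs are flagged and linearly
    interpolated; if more than ``max_flagged_fraction`` of columns are
    flagged the estimate is refused.  ``median_width=3`` applies an
    optional median filter across columns.
    """
    if kymo.source != "mask":
        raise ConfigError("diameter_trace requires a mask kymograph")
    if measure not in ("lumen", "outer"):
        raise ConfigError("measure must be 'lumen' or 'outer'")
    data = kymo.data
    n = data.shape[1]
    diam = np.full(n, np.nan)
    edges = np.full((n, 2), np.nan)
    for i in range(n):
        runs = _column_runs(data[:, i], min_run)
        if len(runs) < 2:
            continue
        lo_run, hi_run = runs[0], runs[-1]
        if measure == "lumen":
            diam[i] = hi_run[0] - lo_run[1] - 1
        else:
            diam[i] = hi_run[1] - lo_run[0] + 1
        edges[i] = (lo_run[1], hi_run[0])
    flagged = np.nonzero(~np.isfinite(diam))[0]
    if flagged.size > max_flagged_fraction * n:
        raise DataError(
            f"{flagged.size}/{n} kymograph columns lack two wall runs; "
            "scan line may not cover both walls")
    if flagged.size:
        log.warning("diameter_trace: interpolated %d flagged column(s)",
                    flagged.size)
        good = np.nonzero(np.isfinite(diam))[0]
        diam[flagged] = np.interp(flagged, good, diam[good])
    if median_width > 1:
        diam = median_filter(diam, size=median_width, mode="nearest")
    dd = normalize_baseline(diam, baseline_frames)
    return DiameterResult(diameter_px=diam, dd_d=dd,
                          flagged_columns=flagged, edges=edges)
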