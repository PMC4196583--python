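"""Two-channel time-lapse stacks: I/O, alignment, binning, background handling.

A :class:`TwoChannelStack` pairs the donor (CFP) and acceptor (YFP) stacks of
one acquisition as ``(frames, height, width)`` arrays with a common frame
interval.  Stacks are stored on disk as one multi-page grayscale TIFF per
channel, page order = time.  ROIs are simple polygons in 0-based pixel
coordinates (x right, y down); membership is by pixel center, rasterized
with ``skimage.draw.polygon2mask``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.draw import polygon2mask

from .errors import ConfigError, DataError, NormalizationError

log = logging.getLogger(__name__)

__all__ = [
    "TwoChannelStack",
    "RoiPolygon",
    "load_rois",
    "read_stack",
    "write_stack",
    "align_channels",
    "bin_stack",
    "subtract_background",
    "normalize_baseline",
]


@dataclass
class TwoChannelStack:
    """Paired donor/acceptor time-lapse arrays with frame timing."""

    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float = 5.0

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor)
        self.acceptor = np.asarray(self.acceptor)
        if self.donor.ndim != 3 or self.acceptor.ndim != 3:
            raise DataError("channel stacks must be (frames, height, width)")
        if self.donor.shape != self.acceptor.shape:
            raise DataError(
                f"channel shapes differ: donor {self.donor.shape} vs "
                f"acceptor {self.acceptor.shape}")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.donor.shape

    @property
    def timestamps(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class RoiPolygon:
    """Simple polygon ROI, vertices as ``[[x, y], ...]`` in pixel coords."""

    vertices: tuple[tuple[float, float], ...]
    label: str = "roi"

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ConfigError(f"ROI '{self.label}': need >= 3 vertices")
        poly = _ShapelyPolygon(verts)
        if not poly.is_valid or poly.area == 0:
            raise ConfigError(
                f"ROI '{self.label}': polygon must be simple with nonzero area")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask of the given (height, width)."""
        # polygon2mask expects (row, col) = (y, x) vertex order
        rc = np.array([(y, x) for x, y in self.vertices])
        if (rc.min() < -0.5 or rc[:, 0].max() > shape[0] - 0.5
                or rc[:, 1].max() > shape[1] - 0.5):
            raise ConfigError(f"ROI '{self.label}' exceeds image bounds {shape}")
        m = polygon2mask(shape, rc)
        if not m.any():
            raise ConfigError(f"ROI '{self.label}' contains no pixel centers")
        return m

    @classmethod
    def rectangle(cls, x0: float, y0: float, x1: float, y1: float,
                  label: str = "roi") -> "RoiPolygon":
        return cls(((x0, y0), (x1, y0), (x1, y1), (x0, y1)), label=label)


def load_rois(path: str | Path) -> dict[str, RoiPolygon]:
    """Read ROI polygons from JSON: ``[{"label":..., "vertices":[[x,y],...]}]``.

    A top-level ``{"rois": [...]}`` wrapper is also accepted.
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = data.get("rois", [data])
    rois = {}
    for entry in data:
        roi = RoiPolygon(tuple(map(tuple, entry["vertices"])),
                         label=entry.get("label", f"roi{len(rois)}"))
        rois[roi.label] = roi
    return rois


def save_rois(rois, path: str | Path) -> None:
    items = rois.values() if isinstance(rois, dict) else rois
    payload = [{"label": r.label, "vertices": [list(v) for v in r.vertices]}
               for r in items]
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# I/O

def read_stack(donor_path: str | Path, acceptor_path: str | Path,
               frame_interval: float = 5.0) -> TwoChannelStack:
    """Load one multi-page TIFF per channel into a :class:`TwoChannelStack`."""
    donor = tifffile.imread(donor_path)
    acceptor = tifffile.imread(acceptor_path)
    donor = np.atleast_3d(donor) if donor.ndim >= 3 else donor[None]
    acceptor = np.atleast_3d(acceptor) if acceptor.ndim >= 3 else acceptor[None]
    if donor.shape != acceptor.shape:
        raise DataError(
            f"channel TIFFs disagree: {donor_path} {donor.shape} vs "
            f"{acceptor_path} {acceptor.shape}")
    return TwoChannelStack(donor, acceptor, frame_interval)


def write_stack(stack: TwoChannelStack, donor_path: str | Path,
                acceptor_path: str | Path) -> None:
    """Write each channel as a multi-page grayscale TIFF (page order = time).

    Integer arrays round-trip bit-exactly; float arrays are written as
    float32 (NaN markers preserved).
    """
    for arr, path in ((stack.donor, donor_path), (stack.acceptor, acceptor_path)):
        out = arr if arr.dtype.kind in "ui" else arr.astype(np.float32)
        tifffile.imwrite(path, out, photometric="minisblack")


# ---------------------------------------------------------------------------
# Alignment

def align_channels(stack: TwoChannelStack, max_shift: int = 5,
                   manual_shift: tuple[int, int] | None = None,
                   ) -> tuple[TwoChannelStack, tuple[int, int]]:
    """Correct a rigid inter-channel offset with one global integer shift.

    The shift ``(dx, dy)`` maximizing the normalized cross-correlation
    between the time-averaged channel images is estimated by brute force
    over a ``(2*max_shift+1)^2`` window, then applied to the acceptor
    channel as a circular shift.  ``manual_shift`` bypasses estimation and
    is applied verbatim.  This corrects channel registration only; it is
    not per-frame motion compensation.
    """
    if max_shift < 0:
        raise ConfigError("max_shift must be >= 0")
    if manual_shift is not None:
        dx, dy = int(manual_shift[0]), int(manual_shift[1])
    else:
        ref = stack.donor.mean(axis=0)
        mov = stack.acceptor.mean(axis=0)
        ref_z = ref - ref.mean()
        best, best_score = (0, 0), -np.inf
        for dy in range(-max_shift, max_shift + 1):
            for dx in range(-max_shift, max_shift + 1):
                shifted = np.roll(mov, (dy, dx), axis=(0, 1))
                sh_z = shifted - shifted.mean()
                denom = np.sqrt((ref_z ** 2).sum() * (sh_z ** 2).sum())
                score = (ref_z * sh_z).sum() / denom if denom > 0 else 0.0
                if score > best_score:
                    best_score, best = score, (dx, dy)
        dx, dy = best
        if max_shift > 0 and (abs(dx) == max_shift or abs(dy) == max_shift):
            warnings.warn(
                f"estimated channel shift ({dx},{dy}) lies on the search "
                f"boundary (max_shift={max_shift}); possible under-correction",
                stacklevel=2)
    aligned = np.roll(stack.acceptor, (dy, dx), axis=(1, 2))
    return (TwoChannelStack(stack.donor.copy(), aligned, stack.frame_interval),
            (dx, dy))


# ---------------------------------------------------------------------------
# Binning

def _bin_axis(arr: np.ndarray, factor: int, axis: int, method: str) -> np.ndarray:
    n = arr.shape[axis]
    keep = (n // factor) * factor
    if keep < n:
        log.info("binning drops %d trailing elements on axis %d", n - keep, axis)
    sl = [slice(None)] * arr.ndim
    sl[axis] = slice(0, keep)
    arr = arr[tuple(sl)]
    new_shape = list(arr.shape)
    new_shape[axis] = keep // factor
    new_shape.insert(axis + 1, factor)
    arr = arr.reshape(new_shape)
    return arr.sum(axis=axis + 1) if method == "sum" else arr.mean(axis=axis + 1)


def bin_stack(stack: TwoChannelStack, spatial_factor: int = 1,
              temporal_factor: int = 1, method: str = "average",
              ) -> TwoChannelStack:
    """Combine non-overlapping pixel blocks / frame groups by sum or average.

    Binning trades spatial or temporal resolution for signal-to-noise.
    Trailing frames/rows/columns that do not fill a block are dropped.
    """
    if method not in ("sum", "average"):
        raise ConfigError("method must be 'sum' or 'average'")
    if spatial_factor < 1 or temporal_factor < 1:
        raise ConfigError("binning factors must be >= 1")
    t, h, w = stack.shape
    if temporal_factor > t or spatial_factor > min(h, w):
        raise ConfigError("binning factor exceeds stack dimension")
    out = []
    for arr in (stack.donor, stack.acceptor):
        a = arr.astype(float)
        if temporal_factor > 1:
            a = _bin_axis(a, temporal_factor, 0, method)
        if spatial_factor > 1:
            a = _bin_axis(a, spatial_factor, 1, method)
            a = _bin_axis(a, spatial_factor, 2, method)
        out.append(a)
    return TwoChannelStack(out[0], out[1],
                           stack.frame_interval * temporal_factor)


# ---------------------------------------------------------------------------
# Background subtraction and baseline normalization

def subtract_background(stack: TwoChannelStack, bg_roi: RoiPolygon,
                        ) -> TwoChannelStack:
    """Subtract the per-frame mean over a background region, per channel.

    Negative results are clamped to zero; the clamped fraction is logged.
    This is the conventional evaluation route; the dynamic-binary-mask
    route (see :mod:`fretmask.segmentation`) deliberately does *not*
    subtract background.
    """
    m = bg_roi.mask(stack.shape[1:])
    out = []
    for arr in (stack.donor, stack.acceptor):
        a = arr.astype(float)
        bg = np.nanmean(np.where(m, a, np.nan), axis=(1, 2))
        corrected = a - bg[:, None, None]
        n_clamped = int((corrected < 0).sum())
        if n_clamped:
            log.info("background subtraction clamped %d negative pixels "
                     "(%.3f%%)", n_clamped, 100 * n_clamped / corrected.size)
        out.append(np.clip(corrected, 0, None))
    return TwoChannelStack(out[0], out[1], stack.frame_interval)


def normalize_baseline(series, baseline_frames) -> np.ndarray:
    """Baseline-normalized change: (x(t) - x_base) / x_base.

    ``baseline_frames`` is an index array or range; the baseline is the
    mean of the series over those frames (NaN gaps skipped).  Applied to a
    fluorescence trace this yields dF/F, to a ratio trace dR/R, and to a
    diameter trace dd/d.  Invariant to multiplicative rescaling of the
    input.
    """
    x = np.asarray(series, dtype=float)
    idx = np.asarray(list(baseline_frames), dtype=int)
    if idx.size == 0:
        raise NormalizationError("baseline_frames is empty")
    if idx.min() < 0 or idx.max() >= x.shape[0]:
        raise NormalizationError("baseline_frames outside series range")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base = np.nanmean(x[idx], axis=0)
    if not np.all(np.isfinite(base)) or np.any(base == 0):
        raise NormalizationError("baseline mean is zero or undefined")
    return (x - base) / base
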