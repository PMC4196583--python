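"""Dynamic binary-mask segmentation and exclusion-aware ratiometry.

The central problem: when a vessel dilates, a fixed ROI drawn around the
wall acquires a growing proportion of dim lumen, so plain ROI means of
both channels drop massively — an artifact that dwarfs the small
FRET-driven intensity changes.  The dynamic binary mask sidesteps this by
thresholding every frame: pixels at or above the threshold keep the value
1, pixels below become an EXCLUDED marker (IEEE NaN — deliberately *not*
zero, so excluded pixels drop out of means instead of dragging them down).
Multiplying the same per-frame mask into both channels yields segmented
stacks in which only the bright target structure carries numbers; ROI
means, ratio images and kymographs then ignore background entirely, and
ROIs may contain arbitrary amounts of background without affecting either
the traces or their noise.

No background subtraction is performed in this mode: background below the
threshold is excluded, and background overlapping the target structure
remains in the kept pixels (which is why this route reports somewhat
smaller dR/R than background subtraction on the same data).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ThresholdError
from .stacks import RoiPolygon, TwoChannelStack, normalize_baseline

log = logging.getLogger(__name__)

EXCLUDED = np.nan
"""Marker for pixels removed by the mask; skipped by all statistics."""

__all__ = [
    "EXCLUDED",
    "BinaryMaskStack",
    "TraceSet",
    "compute_threshold",
    "binary_mask",
    "apply_mask",
    "segment_stack",
    "roi_mean_trace",
    "ratio_stack",
]


@dataclass
class BinaryMaskStack:
    """Per-frame keep/exclude map derived by thresholding one channel."""

    keep: np.ndarray               # boolean, (frames, height, width)
    threshold: float
    source_channel: str = "acceptor"

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 3:
            raise DataError("mask must be (frames, height, width)")

    @property
    def counted_per_frame(self) -> np.ndarray:
        return self.keep.sum(axis=(1, 2))

    def as_float(self) -> np.ndarray:
        """1.0 / NaN representation, as written to 32-bit float TIFF."""
        out = np.full(self.keep.shape, EXCLUDED, dtype=np.float32)
        out[self.keep] = 1.0
        return out


@dataclass
class TraceSet:
    """Per-frame channel means, ratio and baseline-normalized changes."""

    frame: np.ndarray
    time_s: np.ndarray
    donor_mean: np.ndarray
    acceptor_mean: np.ndarray
    ratio: np.ndarray
    dff_donor: np.ndarray
    dff_acceptor: np.ndarray
    drr: np.ndarray
    counted_px: np.ndarray
    mode: str = "segmentation"
    baseline_frames: tuple[int, ...] = ()
    diameter_px: np.ndarray | None = None
    dd_d: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "frame": self.frame, "time_s": self.time_s,
            "cfp_mean": self.donor_mean, "yfp_mean": self.acceptor_mean,
            "ratio": self.ratio, "dFF_cfp": self.dff_donor,
            "dFF_yfp": self.dff_acceptor, "dRR": self.drr,
            "counted_px": self.counted_px,
        })
        if self.diameter_px is not None:
            df["diameter_px"] = self.diameter_px
            df["dd_d"] = self.dd_d
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _otsu_exact(values: np.ndarray) -> float:
    """Otsu's threshold by exact sweep over the pooled unique values.

    Binned Otsu implementations can return a value inside a histogram bin,
    leaving the pixels of that bin ambiguously classified under an
    inclusive keep-rule.  Sweeping the exact value histogram instead, the
    returned threshold is the midpoint between the optimal background
    class's maximum and the foreground class's minimum, so ``>=`` keeps
    precisely Otsu's foreground.
    """
    vals, counts = np.unique(values, return_counts=True)
    if vals.size < 2:
        raise ThresholdError("cannot compute Otsu threshold on a constant stack")
    w = counts.astype(float)
    cw = np.cumsum(w)
    cs = np.cumsum(w * vals)
    total_w, total_s = cw[-1], cs[-1]
    # split after index k: background = vals[:k+1], foreground = vals[k+1:]
    w0, s0 = cw[:-1], cs[:-1]
    w1, s1 = total_w - w0, total_s - s0
    between = w0 * w1 * (s0 / w0 - s1 / w1) ** 2
    k = int(np.argmax(between))
    return float(0.5 * (vals[k] + vals[k + 1]))


def compute_threshold(channel_stack: np.ndarray, method: str = "otsu",
                      manual_value: float | None = None) -> float:
    """Lower intensity threshold separating target structure from background.

    ``otsu`` is computed on the pooled histogram of *all* frames (the
    stack histogram), so one threshold serves the whole time series and
    the structure must stay above it throughout — including frames where
    FRET changes dim the masked channel.  ``manual`` returns the supplied
    value unchanged.
    """
    arr = np.asarray(channel_stack, dtype=float)
    if method == "manual":
        if manual_value is None:
            raise ConfigError("manual thresholding requires a value")
        return float(manual_value)
    if method != "otsu":
        raise ConfigError(f"unknown threshold method '{method}'")
    finite = arr[np.isfinite(arr)]
    if finite.size == 0 or np.ptp(finite) == 0:
        raise ThresholdError("cannot compute Otsu threshold on a constant stack")
    return _otsu_exact(finite.ravel())


def binary_mask(channel_stack: np.ndarray, threshold: float,
                source_channel: str = "acceptor") -> BinaryMaskStack:
    """Dynamic binary mask: >= threshold -> keep (1), below -> EXCLUDED.

    The mask is recomputed for every frame from the same global threshold,
    so it follows moving structures.  Frames in which no pixel passes are
    flagged with a warning.
    """
    arr = np.asarray(channel_stack, dtype=float)
    if not np.isfinite(threshold):
        raise ConfigError("threshold must be finite")
    keep = arr >= threshold
    empty = np.nonzero(~keep.any(axis=(1, 2)))[0]
    if empty.size:
        warnings.warn(f"{empty.size} frame(s) have no above-threshold pixels: "
                      f"{empty[:10].tolist()}", stacklevel=2)
    return BinaryMaskStack(keep, float(threshold), source_channel)


def apply_mask(stack: TwoChannelStack, mask: BinaryMaskStack,
               ) -> TwoChannelStack:
    """Multiply the same mask into both channels.

    Kept pixels retain their raw intensities; excluded pixels become NaN.
    Background is excluded, never subtracted, in this mode.
    """
    if mask.keep.shape != stack.shape:
        raise DataError(f"mask shape {mask.keep.shape} != stack {stack.shape}")
    donor = np.where(mask.keep, stack.donor.astype(float), EXCLUDED)
    acceptor = np.where(mask.keep, stack.acceptor.astype(float), EXCLUDED)
    return TwoChannelStack(donor, acceptor, stack.frame_interval)


def _mask_source(stack: TwoChannelStack, channel: str) -> np.ndarray:
    if channel == "donor":
        return stack.donor
    if channel == "acceptor":
        return stack.acceptor
    if channel == "sum":
        return stack.donor + stack.acceptor
    raise ConfigError("mask channel must be 'donor', 'acceptor' or 'sum'")


def segment_stack(stack: TwoChannelStack, threshold: float | None = None,
                  method: str = "otsu", mask_channel: str = "acceptor",
                  baseline_frames=None, guard_fraction: float = 0.2,
                  ) -> tuple[TwoChannelStack, BinaryMaskStack]:
    """Threshold one channel, build the mask, and apply it to both channels.

    The default mask source is the acceptor channel, brightest at the
    high-FRET (low-cGMP) baseline.  A guard warns if any frame's kept-pixel
    count falls more than ``guard_fraction`` below the baseline count —
    the telltale of FRET-driven dimming pushing the structure below the
    threshold, which invalidates the mask.
    """
    src = _mask_source(stack, mask_channel)
    thr = compute_threshold(src, "manual" if threshold is not None else method,
                            manual_value=threshold)
    mask = binary_mask(src, thr, mask_channel)
    counted = mask.counted_per_frame
    if baseline_frames is not None:
        idx = np.asarray(list(baseline_frames), dtype=int)
        ref = counted[idx].mean()
        low = np.nonzero(counted < (1.0 - guard_fraction) * ref)[0]
        if ref > 0 and low.size:
            warnings.warn(
                f"kept-pixel count drops >{guard_fraction:.0%} below baseline "
                f"in {low.size} frame(s) (e.g. {low[:5].tolist()}); structure "
                f"may be falling below the threshold", stacklevel=2)
    return apply_mask(stack, mask), mask


def roi_mean_trace(stack: TwoChannelStack, roi: RoiPolygon, baseline_frames,
                   mode: str = "segmentation") -> TraceSet:
    """Exclusion-aware per-frame channel means, ratio, dF/F and dR/R.

    Only counted (non-excluded) pixels inside the ROI contribute to the
    means, so the ROI may contain any amount of excluded background
    without changing the trace or its noise.  Frames with zero counted
    pixels yield NaN gaps and a warning.
    """
    m = roi.mask(stack.shape[1:])
    donor = stack.donor.astype(float)[:, m]
    acceptor = stack.acceptor.astype(float)[:, m]
    counted = np.isfinite(donor).sum(axis=1)
    gaps = np.nonzero(counted == 0)[0]
    if gaps.size:
        warnings.warn(f"ROI '{roi.label}': {gaps.size} frame(s) have zero "
                      f"counted pixels; trace gap at {gaps[:10].tolist()}",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d_mean = np.nanmean(donor, axis=1)
        a_mean = np.nanmean(acceptor, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(a_mean > 0, d_mean / a_mean, np.nan)
    baseline = tuple(int(i) for i in baseline_frames)
    return TraceSet(
        frame=np.arange(stack.n_frames),
        time_s=stack.timestamps,
        donor_mean=d_mean, acceptor_mean=a_mean, ratio=ratio,
        dff_donor=normalize_baseline(d_mean, baseline),
        dff_acceptor=normalize_baseline(a_mean, baseline),
        drr=normalize_baseline(ratio, baseline),
        counted_px=counted, mode=mode, baseline_frames=baseline)


def ratio_stack(segmented: TwoChannelStack) -> tuple[np.ndarray, dict]:
    """Pixel-wise donor/acceptor ratio of segmented stacks.

    The ratio is computed only where both channels carry counted pixels;
    everything else stays EXCLUDED, so the noisy-division artifacts of
    ratioing raw images never arise.  Acceptor pixels equal to zero are
    excluded and tallied in the returned diagnostics.
    """
    donor = segmented.donor.astype(float)
    acceptor = segmented.acceptor.astype(float)
    both = np.isfinite(donor) & np.isfinite(acceptor)
    zero_div = both & (acceptor == 0)
    valid = both & (acceptor != 0)
    out = np.full(donor.shape, EXCLUDED, dtype=float)
    out[valid] = donor[valid] / acceptor[valid]
    diags = {"zero_division_px": int(zero_div.sum()),
             "counted_px": int(valid.sum())}
    if zero_div.any():
        log.info("ratio_stack: %d zero-acceptor pixels excluded",
                 diags["zero_division_px"])
    return out, diags
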