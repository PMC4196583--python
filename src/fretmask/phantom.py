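"""Synthetic dilating-vessel phantom with per-frame ground truth.

The phantom emulates what the analysis pipeline faces in vivo: a vessel
wall expressing a cGMP FRET sensor, embedded in dim tissue, that dilates
in response to drug-induced cGMP transients while being imaged in two
channels.  It renders a 2-D projection of a tube as two parallel wall
bands around a dim lumen, on a dim tissue background, and supports:

* exponential-pulse cGMP transients (bolus drug applications),
* sigmoid cGMP->dilation coupling with optional lag, plus an optional
  "saline bump" — transient dilation with no cGMP change (volume effect),
* symmetric or single-wall (asymmetric) dilation,
* Poisson shot noise + Gaussian read noise, photobleaching, rigid
  per-frame jitter, fixed inter-channel misalignment, spectral crosstalk
  (via the sensor parameters), and bright striated-muscle overlay patches.

Every run returns a :class:`PhantomTruth` with the ground-truth cGMP
concentration, lumen diameter and wall ratio per frame, so each pipeline
stage can be validated quantitatively without animal data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sensor as _sensor
from .errors import ConfigError
from .sensor import SensorParams
from .stacks import TwoChannelStack

log = logging.getLogger(__name__)

__all__ = [
    "Pulse",
    "Coupling",
    "SalineBump",
    "PhantomConfig",
    "PhantomTruth",
    "cgmp_trajectory",
    "diameter_trajectory",
    "simulate_timelapse",
]


@dataclass(frozen=True)
class Pulse:
    """One drug application: cGMP rises toward ``c_max_nM`` with time
    constant ``tau_on_s`` for ``duration_s``, then decays with
    ``tau_off_s``.  ``tau -> 0`` gives a rectangular profile."""

    start_frame: int
    c_max_nM: float
    tau_on_s: float = 10.0
    tau_off_s: float = 30.0
    duration_s: float = 30.0

    def __post_init__(self) -> None:
        if self.c_max_nM < 0 or self.tau_on_s < 0 or self.tau_off_s < 0:
            raise ConfigError("pulse amplitudes and time constants must be >= 0")
        if self.duration_s <= 0:
            raise ConfigError("pulse duration must be > 0")


@dataclass(frozen=True)
class Coupling:
    """Sigmoid cGMP -> dilation coupling:
    d(t) = d_base * (1 + g_max * h(c(t - lag))), h a Hill curve at K_dil."""

    g_max: float = 0.3
    k_dil_nM: float = 500.0
    hill: float = 2.0
    lag_s: float = 0.0

    def __post_init__(self) -> None:
        if self.g_max < 0 or self.k_dil_nM <= 0 or self.hill <= 0 or self.lag_s < 0:
            raise ConfigError("invalid coupling parameters")


@dataclass(frozen=True)
class SalineBump:
    """Transient dilation with zero cGMP change (blood-volume effect of a
    vehicle bolus), shaped as a raised cosine."""

    start_frame: int
    amplitude: float = 0.15      # relative diameter increase at peak
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.duration_s <= 0:
            raise ConfigError("invalid saline bump parameters")


@dataclass
class PhantomConfig:
    """Scene, optics, noise and stimulus description of one simulation.

    Brightness fields are expected photon counts per pixel; the sensor's
    emission coefficients scale ``wall_brightness`` per channel.  Tissue
    and lumen backgrounds are sensor-free fluorescence, identical in both
    channels; ``ambient_background`` is added to *every* pixel (including
    the wall) and models tissue autofluorescence overlapping the target —
    the term that background subtraction removes but segmentation keeps.
    """

    width: int = 80
    height: int = 64
    n_frames: int = 60
    frame_interval: float = 5.0
    orientation: str = "vertical"        # vessel axis: vertical | horizontal
    d_base: float = 20.0                 # baseline lumen diameter, px
    wall_thickness: float = 4.0          # px
    dilation_mode: str = "symmetric"     # symmetric | upper
    wall_brightness: float = 1000.0
    tissue_background: float = 80.0
    lumen_background: float = 20.0
    ambient_background: float = 0.0
    striated_patches: tuple = ()         # (row0, col0, row1, col1) rectangles
    striated_brightness: float = 3000.0
    dark_patches: tuple = ()             # rectangles of non-fluorescent tissue
    poisson_noise: bool = True
    read_noise_sigma: float = 2.0
    bleach_rate: float = 0.0             # per-frame exponential decay constant
    jitter_sigma: float = 0.0            # px, rigid per-frame translation
    channel_misalignment: tuple[int, int] = (0, 0)   # (dx, dy) on acceptor
    pulses: tuple[Pulse, ...] = ()
    coupling: Coupling = field(default_factory=Coupling)
    saline_bump: SalineBump | None = None
    sensor: SensorParams = field(default_factory=SensorParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.orientation not in ("vertical", "horizontal"):
            raise ConfigError("orientation must be 'vertical' or 'horizontal'")
        if self.dilation_mode not in ("symmetric", "upper"):
            raise ConfigError("dilation_mode must be 'symmetric' or 'upper'")
        for name in ("d_base", "wall_thickness", "wall_brightness",
                     "tissue_background", "lumen_background",
                     "ambient_background", "read_noise_sigma", "bleach_rate",
                     "jitter_sigma", "frame_interval"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        extent = self.width if self.orientation == "vertical" else self.height
        if self.d_base + 2 * self.wall_thickness >= extent:
            raise ConfigError("vessel does not fit across the field of view")

    @property
    def cross_extent(self) -> int:
        """Pixels across the vessel (the diameter axis)."""
        return self.width if self.orientation == "vertical" else self.height


@dataclass
class PhantomTruth:
    """Ground truth per frame: concentration, diameter, wall ratio."""

    time_s: np.ndarray
    cgmp_nM: np.ndarray
    diameter_px: np.ndarray
    true_ratio: np.ndarray
    wall_masks: np.ndarray      # boolean (frames, height, width)

    def __post_init__(self) -> None:
        n = self.time_s.shape[0]
        for name in ("cgmp_nM", "diameter_px", "true_ratio"):
            if getattr(self, name).shape[0] != n:
                raise ConfigError(f"truth field {name} length != n_frames")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.time_s.size), "time_s": self.time_s,
            "cgmp_nM": self.cgmp_nM, "diameter_px": self.diameter_px,
            "true_ratio": self.true_ratio,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def cgmp_trajectory(pulses, n_frames: int, frame_interval: float) -> np.ndarray:
    """Per-frame cGMP concentration (nM) from a list of pulses.

    Each pulse rises as c_max*(1 - exp(-t/tau_on)) during its application
    window and decays exponentially with tau_off afterwards.  Overlapping
    pulses are summed (and logged), mirroring additive drug effects.
    """
    t = np.arange(n_frames) * frame_interval
    c = np.zeros(n_frames)
    active = np.zeros(n_frames, dtype=int)
    for p in pulses:
        if not (0 <= p.start_frame < n_frames):
            raise ConfigError(f"pulse start frame {p.start_frame} out of range")
        t0 = p.start_frame * frame_interval
        dt_on = t - t0
        dt_off = t - (t0 + p.duration_s)
        if p.tau_on_s > 0:
            rise = p.c_max_nM * (1.0 - np.exp(-np.maximum(dt_on, 0.0)
                                              / p.tau_on_s))
        else:
            rise = np.full_like(t, p.c_max_nM)
        c_end = (p.c_max_nM * (1.0 - np.exp(-p.duration_s / p.tau_on_s))
                 if p.tau_on_s > 0 else p.c_max_nM)
        if p.tau_off_s > 0:
            fall = c_end * np.exp(-np.maximum(dt_off, 0.0) / p.tau_off_s)
        else:
            fall = np.zeros_like(t)
        contrib = np.where(dt_on < 0, 0.0, np.where(dt_off < 0, rise, fall))
        active += (contrib > 0.01 * p.c_max_nM).astype(int)
        c += contrib
    n_overlap = int((active > 1).sum())
    if n_overlap:
        log.warning("cgmp_trajectory: %d frame(s) with overlapping pulses "
                    "(contributions summed)", n_overlap)
    return c


def diameter_trajectory(c_series: np.ndarray, config: PhantomConfig,
                        ) -> np.ndarray:
    """Per-frame lumen diameter (px) from the concentration series."""
    cp = config.coupling
    lag_frames = int(round(cp.lag_s / config.frame_interval))
    c_lag = np.concatenate([np.zeros(lag_frames),
                            np.asarray(c_series)[:len(c_series) - lag_frames]]) \
        if lag_frames > 0 else np.asarray(c_series, dtype=float)
    h = c_lag ** cp.hill / (cp.k_dil_nM ** cp.hill + c_lag ** cp.hill)
    d = config.d_base * (1.0 + cp.g_max * h)
    if config.saline_bump is not None:
        sb = config.saline_bump
        t = np.arange(len(c_series)) * config.frame_interval
        phase = (t - sb.start_frame * config.frame_interval) / sb.duration_s
        bump = np.where((phase >= 0) & (phase <= 1),
                        0.5 * (1.0 - np.cos(2 * np.pi * phase)), 0.0)
        d = d + config.d_base * sb.amplitude * bump
    return d


def _wall_lumen_profiles(config: PhantomConfig, d: float, offset: float,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean wall / lumen membership along the diameter axis.

    Pixel-center convention: lumen is strictly between the inner wall
    edges; each wall band spans ``wall_thickness`` outward from its edge.
    """
    n = config.cross_extent
    u = np.arange(n, dtype=float)
    c0 = (n - 1) / 2.0 + offset
    if config.dilation_mode == "symmetric":
        lo = c0 - d / 2.0
        hi = c0 + d / 2.0
    else:  # 'upper': lower edge fixed at baseline position, upper wall moves
        lo = c0 - config.d_base / 2.0
        hi = lo + d
    w = config.wall_thickness
    if lo - w < -0.5 or hi + w > n - 0.5:
        raise ConfigError(
            f"geometry overflow: vessel (d={d:.1f} px) leaves the field")
    lumen = (u > lo) & (u < hi)
    wall = ((u > lo - w) & (u <= lo)) | ((u >= hi) & (u < hi + w))
    return wall, lumen


def simulate_timelapse(config: PhantomConfig,
                       ) -> tuple[TwoChannelStack, PhantomTruth]:
    """Render the phantom and return the stack plus ground truth.

    Deterministic for a given seed (bit-identical reruns).  With noise,
    jitter and pulses all off, every frame is identical.
    """
    rng = np.random.default_rng(config.seed)
    c_series = cgmp_trajectory(config.pulses, config.n_frames,
                               config.frame_interval)
    d_series = diameter_trajectory(c_series, config)
    donor_e, acceptor_e = _sensor.channel_intensities(
        c_series, config.wall_brightness, config.sensor)
    true_ratio = np.asarray(donor_e) / np.asarray(acceptor_e)

    h, w = config.height, config.width
    donor = np.empty((config.n_frames, h, w))
    acceptor = np.empty_like(donor)
    wall_masks = np.zeros((config.n_frames, h, w), dtype=bool)

    if config.jitter_sigma > 0:
        jit = np.rint(rng.normal(0.0, config.jitter_sigma,
                                 size=(config.n_frames, 2))).astype(int)
    else:
        jit = np.zeros((config.n_frames, 2), dtype=int)

    for i in range(config.n_frames):
        bleach = np.exp(-config.bleach_rate * i)
        off_cross = jit[i, 0]
        off_axial = jit[i, 1]
        wall1d, lumen1d = _wall_lumen_profiles(config, d_series[i], off_cross)
        bg1d = np.where(lumen1d, config.lumen_background,
                        config.tissue_background)
        d_prof = np.where(wall1d, donor_e[i] * bleach, bg1d * bleach)
        a_prof = np.where(wall1d, acceptor_e[i] * bleach, bg1d * bleach)
        d_prof = d_prof + config.ambient_background * bleach
        a_prof = a_prof + config.ambient_background * bleach
        if config.orientation == "vertical":
            frame_d = np.broadcast_to(d_prof, (h, w)).copy()
            frame_a = np.broadcast_to(a_prof, (h, w)).copy()
            wall_masks[i] = np.broadcast_to(wall1d, (h, w))
        else:
            frame_d = np.broadcast_to(d_prof[:, None], (h, w)).copy()
            frame_a = np.broadcast_to(a_prof[:, None], (h, w)).copy()
            wall_masks[i] = np.broadcast_to(wall1d[:, None], (h, w))
        for (r0, c0p, r1, c1p) in config.dark_patches:
            # non-fluorescent area (e.g. another vessel's lumen or a shadow):
            # background drops to the lumen level; wall pixels are untouched
            sl = (slice(max(r0 + off_axial, 0), max(r1 + off_axial, 0)),
                  slice(max(c0p, 0), max(c1p, 0)))
            dark = (config.lumen_background + config.ambient_background) * bleach
            wall2d = wall_masks[i][sl]
            frame_d[sl] = np.where(wall2d, frame_d[sl], dark)
            frame_a[sl] = np.where(wall2d, frame_a[sl], dark)
        for (r0, c0p, r1, c1p) in config.striated_patches:
            sl = (slice(max(r0 + off_axial, 0), max(r1 + off_axial, 0)),
                  slice(max(c0p, 0), max(c1p, 0)))
            frame_d[sl] += config.striated_brightness * bleach
            frame_a[sl] += config.striated_brightness * bleach
        donor[i], acceptor[i] = frame_d, frame_a

    if config.poisson_noise:
        donor = rng.poisson(donor).astype(float)
        acceptor = rng.poisson(acceptor).astype(float)
    if config.read_noise_sigma > 0:
        donor = donor + rng.normal(0, config.read_noise_sigma, donor.shape)
        acceptor = acceptor + rng.normal(0, config.read_noise_sigma,
                                         acceptor.shape)
        donor = np.clip(donor, 0, None)
        acceptor = np.clip(acceptor, 0, None)

    dx, dy = config.channel_misalignment
    if (dx, dy) != (0, 0):
        acceptor = np.roll(acceptor, (dy, dx), axis=(1, 2))

    stack = TwoChannelStack(donor, acceptor, config.frame_interval)
    truth = PhantomTruth(
        time_s=np.arange(config.n_frames) * config.frame_interval,
        cgmp_nM=c_series, diameter_px=d_series, true_ratio=true_ratio,
        wall_masks=wall_masks)
    return stack, truth
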