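# Methods

This note documents the models, defaults and numerical conventions behind
`fretmask`. The package is self-validating: every quantitative claim below
is enforced by a test in `tests/`.

## 1. Sensor model (`fretmask.sensor`)

The biosensor is modeled as a two-state system. Ligand occupancy follows a
Hill curve; with optional cross-binding by a second ligand (cAMP) as
competing occupancy:

    x = (c / EC50_cGMP)^n + (a / EC50_cAMP)^n,     f = x / (1 + x)

Channel emissions upon donor excitation interpolate linearly between the
unbound and bound states and add the two crosstalk terms:

    donor    = B [ (1-f) d0 + f d1 ]
    acceptor = B [ (1-f) a0 + f a1 ] + beta * donor + delta * B * a0

with `B` an arbitrary brightness, `beta` the donor-into-acceptor
bleed-through and `delta` direct acceptor excitation.

Defaults: `EC50_cGMP = 500 nM`, `n = 2` (two tandem binding sites, and
consistent with a ~100 nM detection floor and ~3 µM saturation for a
500 nM-EC50 sensor), `d0 = 0.8`, `d1 = 1.0`, `a0 = 1.0`, `a1 = 5/6`,
`beta = delta = 0`. These are calibrated so the CFP/YFP ratio runs from
exactly 0.8 (unbound) to exactly 1.2 (saturated), i.e. a saturating
ΔR/R of exactly 50% — the anchor for acceptance target t2. Both crosstalk
terms strictly compress the apparent ΔR/R (acceptance criterion 7), which
is the qualitative reason a sensor that shows ~50% in a cuvette can show
~10% in tissue.

### EC50 identifiability and the titration fit

The ratio of the two emissions reduces *exactly* to a four-parameter
logistic in concentration:

    R(c) = (R_u + R_s x) / (1 + x),   x = (c / EC50_app)^n,
    EC50_app = EC50 * (1 + gamma)^(-1/n),   gamma = (a1 - a0) / a0

The binding EC50 and the acceptor curvature `gamma` are therefore **not
jointly identifiable from ratio data**: any (EC50, gamma) pair with the
same `EC50_app` produces bit-identical curves. `fit_titration` fits the
logistic with `scipy.optimize.curve_fit` (x-scaled, tolerances 1e-14) and
converts the apparent midpoint to the binding EC50 using `gamma` as a
known sensor constant (default −1/6 from the emission defaults). Fitting a
naive 5-parameter two-state model instead leaves the fit degenerate and
biases the recovered EC50 by the optimizer's path. With the correction,
the end-to-end pipeline recovers 500 nM to ~1e-13 relative (target t1).

## 2. Phantom (`fretmask.phantom`)

A vertical (or horizontal) vessel rendered as two bright wall bands of a
given thickness around a dim lumen, in a field of dim tissue. Rendering is
1-D across the vessel and broadcast along it; membership is by pixel
center, with the lumen strictly between the continuous inner wall edges.
Per frame:

* cGMP follows a sum of pulses with exponential rise during application
  and exponential decay afterwards (`Pulse`: start, peak, tau_on, tau_off,
  duration). Overlapping pulses sum and are logged.
* Diameter couples to cGMP through a Hill function with gain `g_max` and
  optional lag; an optional `SalineBump` dilates the vessel with *no* cGMP
  change (the negative-control scenario for artifact tests).
* Wall pixels emit sensor light only; `ambient_background` adds a common
  term to **all** pixels including walls — the component that background
  subtraction can remove but segmentation deliberately keeps.
  `dark_patches` are non-fluorescent rectangles (background at lumen
  level) usable as background-ROI targets; `striated_patches` are bright
  overlays that also break the vessel's translational symmetry.
* Noise: Poisson on the expected counts, then Gaussian read noise, then a
  clip at zero. Bleaching multiplies both channels by exp(-rate * frame)
  (equal bleaching leaves the ratio unchanged — tested). Motion jitter is
  an integer per-frame shift; channel misalignment is an integer circular
  shift of the acceptor.

Ground truth (`PhantomTruth`) carries cGMP, diameter, the true sensor
ratio and per-frame wall masks.

Realism limits: integer-pixel geometry and motion (no partial-volume
edges), uniform wall emission, a single global misalignment, no focal
drift, no flowing-cell shadows. These keep every truth quantity exact,
which is what the acceptance tolerances are anchored to.

## 3. Preprocessing and segmentation

Fixed order: **align → bin → mode-specific background handling →
segmentation / ratiometry**.

* Alignment estimates one global integer shift by brute-force normalized
  cross-correlation on time-averaged channels (±`max_shift` window) and
  applies it to the acceptor. Note the degenerate case: an image that is
  translation-invariant along one axis (e.g. a perfectly vertical vessel)
  leaves that shift component undetermined.
* Binning combines non-overlapping blocks by sum or average, dropping
  trailing remainders (logged).
* `bgsub` mode subtracts the per-frame mean of a background ROI from each
  channel and clamps at zero. `segmentation` mode performs **no**
  background subtraction and refuses a background ROI outright: below the
  threshold, background is excluded; above it (e.g. ambient light on the
  walls), it is part of the signal — which is why segmentation reports a
  somewhat smaller ΔR/R than subtraction on the same data (criterion 6).

### Threshold and mask conventions

* The Otsu threshold is computed on the **pooled histogram of all frames**,
  so one threshold serves the whole series; a guard warns if any frame's
  kept-pixel count drops more than 20% below the baseline count (the
  telltale of FRET-driven dimming pushing the structure under the
  threshold — prefer the acceptor channel, brightest at baseline, or a
  `sum` mask).
* Otsu is an **exact sweep over the pooled unique values**, returning the
  midpoint between the optimal background class's maximum and foreground
  class's minimum. Binned implementations can return a value *inside* a
  histogram bin, making classification of that bin ambiguous under the
  inclusive keep rule (observed: a binned threshold of 79.3 with a
  background class at 80, which silently kept the tissue).
* The keep rule is inclusive: `pixel >= threshold` keeps. Excluded pixels
  are IEEE NaN, never zero, and the same mask multiplies both channels.
* ROI traces are NaN-excluding means; the ratio trace is the ratio of the
  two channel means (not the mean of pixel ratios). ΔF/F, ΔR/R and Δd/d
  are all `(x - baseline mean) / baseline mean`.
* The pixel-wise ratio map divides only where both channels are counted
  and the acceptor is nonzero; zero-acceptor pixels are excluded and
  tallied in diagnostics.

## 4. Kymograph diameter (`fretmask.kymograph`)

The mask stack is resliced along a scan line (~1 px sample spacing) with
nearest-neighbor sampling — kept/excluded states are never blended.
Per column, kept runs shorter than `min_run = 2` are discarded as speckle,
the two outermost remaining runs are the walls, and the default diameter
is the **lumen count**: excluded pixels strictly between the walls' inner
edges (an `outer` edge-to-edge measure is available). Columns with fewer
than two wall runs are flagged and linearly interpolated; if more than 10%
of columns are flagged the estimate is refused (`DataError`). An optional
median filter (`median_width = 3`) smooths single-frame speckle.
Performance on the phantom: max error ≤ 1 px noise-free, RMSE ≤ 2 px at
default noise, Pearson r > 0.99 against true Δd/d (criterion 5).

## 5. Method comparison (`compare_methods`)

For a `mode: both` run, per method and ROI: peak |ΔF/F| (the magnitude of
the motion artifact), peak ΔR/R, and the ΔR/R variance/SD over a static
window. Whether the artifact leaks into the masked ratio is probed **at a
single frame** — the frame where the bgsub intensity artifact peaks
(`segmentation_drr_at_artifact`) — rather than as a max over the whole
response window, because the maximum of ~40 noise samples exceeds 3σ about
10% of the time even with zero artifact; the single-frame probe makes the
3σ criterion meaningful (criterion 4).

## 6. Problem sizes and determinism

Default phantom: 80×64 px, 40–80 frames at 5 s — seconds to simulate and
analyze; the full test suite runs in well under a minute on one CPU, and
`scripts/acceptance.py` in a few seconds. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; reruns are
bit-identical, and noise-free configurations are deterministic
independent of seed.
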