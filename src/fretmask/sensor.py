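"""Photophysical model of the cGi500 FRET biosensor.

cGi500 is a monomolecular cGMP indicator: two tandem cGMP-binding sites
flanked by CFP (donor) and YFP (acceptor).  Without cGMP the fluorophores
FRET efficiently, so donor excitation yields strong acceptor (YFP, 535 nm)
emission; cGMP binding lowers FRET efficiency, raising donor (CFP, 480 nm)
emission and lowering acceptor emission.  The readout is the emission ratio
R = CFP/YFP, which rises monotonically with cGMP.

The model here is a two-state equilibrium: a Hill occupancy f(c) mixes
unbound and fully-bound emission coefficients linearly in each channel.
Optical crosstalk is modelled with two terms that both compress the
apparent ratio change:

* ``beta`` — bleed-through: a fraction of donor emission detected in the
  acceptor channel;
* ``delta`` — direct acceptor excitation: acceptor emission (a fraction of
  the unbound acceptor coefficient) present regardless of FRET state.

Defaults are calibrated so that the unbound ratio is 0.8, the saturated
ratio is 1.2 and hence the saturating baseline-normalized ratio change
dR/R is exactly 50%, matching the sensor's published dynamic range; any
common positive rescaling of the emission coefficients is equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigError, FitError

__all__ = [
    "SensorParams",
    "fraction_bound",
    "channel_intensities",
    "ratio",
    "saturating_drr",
    "fit_titration",
    "TitrationFit",
]


@dataclass(frozen=True)
class SensorParams:
    """Photophysical constants of the two-state ratio model.

    Parameters
    ----------
    ec50_cgmp : float
        Half-maximal cGMP concentration in nM. Default 500.
    hill_n : float
        Hill coefficient of cGMP binding. The sensor carries tandem
        binding sites; n=2 together with EC50 = 500 nM puts occupancy at
        ~4% near the 100 nM detection floor and ~97% at the ~3 uM
        saturation point.
    d0, d1 : float
        Donor-channel emission coefficients (arbitrary units per sensor
        per exposure) in the unbound / fully bound state; d1 > d0.
    a0, a1 : float
        Acceptor-channel emission coefficients, unbound / bound; a1 < a0.
    beta : float
        Bleed-through fraction of donor emission detected in the acceptor
        channel, in [0, 1).
    delta : float
        Direct acceptor-excitation term: fraction of ``a0`` added to the
        acceptor channel regardless of FRET state, in [0, 1).
    ec50_camp : float
        Half-maximal cAMP cross-binding concentration in uM. The sensor
        responds to cAMP only far above physiological levels; cross-binding
        is off unless a cAMP concentration is passed explicitly.
    """

    ec50_cgmp: float = 500.0
    hill_n: float = 2.0
    d0: float = 0.8
    d1: float = 1.0
    a0: float = 1.0
    a1: float = 5.0 / 6.0
    beta: float = 0.0
    delta: float = 0.0
    ec50_camp: float = 100.0

    def __post_init__(self) -> None:
        if self.ec50_cgmp <= 0:
            raise ConfigError("ec50_cgmp must be > 0")
        if self.hill_n <= 0:
            raise ConfigError("hill_n must be > 0")
        if min(self.d0, self.d1, self.a0, self.a1) <= 0:
            raise ConfigError("emission coefficients must be > 0")
        if not self.d1 > self.d0:
            raise ConfigError("d1 must exceed d0 (binding raises donor emission)")
        if not self.a1 < self.a0:
            raise ConfigError("a1 must be below a0 (binding lowers acceptor emission)")
        if not (0.0 <= self.beta < 1.0):
            raise ConfigError("beta must lie in [0, 1)")
        if not (0.0 <= self.delta < 1.0):
            raise ConfigError("delta must lie in [0, 1)")
        if self.ec50_camp <= 0:
            raise ConfigError("ec50_camp must be > 0")


def fraction_bound(c, params: SensorParams = SensorParams(), camp: float = 0.0):
    """Equilibrium occupancy of the sensor at cGMP concentration ``c`` (nM).

    Hill binding: f = c^n / (EC50^n + c^n). Binding kinetics are fast
    relative to acquisition, so equilibrium is assumed frame by frame.

    ``camp`` (uM) optionally adds cAMP cross-binding as a second Hill term
    competing for the same reporter state:
    x = (c/EC50_cGMP)^n + (camp/EC50_cAMP)^n, f = x/(1+x).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ConfigError("cGMP concentration must be >= 0")
    if camp < 0:
        raise ConfigError("cAMP concentration must be >= 0")
    x = (c / params.ec50_cgmp) ** params.hill_n
    if camp > 0:
        x = x + (camp / params.ec50_camp) ** params.hill_n
    f = x / (1.0 + x)
    return f if f.ndim else float(f)


def channel_intensities(c, brightness, params: SensorParams = SensorParams(),
                        camp: float = 0.0):
    """Measured donor and acceptor intensities at concentration ``c``.

    ``brightness`` B is sensor abundance x excitation x exposure (counts).
    With occupancy f:

    * donor   = B * [(1-f) d0 + f d1]
    * acceptor = B * [(1-f) a0 + f a1] + beta * donor + delta * B * a0

    Returns ``(donor, acceptor)``, broadcast over array inputs.
    """
    b = np.asarray(brightness, dtype=float)
    if np.any(b < 0):
        raise ConfigError("brightness must be >= 0")
    f = np.asarray(fraction_bound(c, params, camp=camp))
    donor = b * ((1.0 - f) * params.d0 + f * params.d1)
    acceptor = (b * ((1.0 - f) * params.a0 + f * params.a1)
                + params.beta * donor + params.delta * b * params.a0)
    if donor.ndim == 0:
        return float(donor), float(acceptor)
    return donor, acceptor


def ratio(c, params: SensorParams = SensorParams(), camp: float = 0.0):
    """Donor/acceptor emission ratio R(c); independent of brightness."""
    donor, acceptor = channel_intensities(c, 1.0, params, camp=camp)
    r = np.asarray(donor) / np.asarray(acceptor)
    return r if r.ndim else float(r)


def saturating_drr(params: SensorParams = SensorParams()) -> float:
    """Baseline-normalized ratio change R(inf)/R(0) - 1 at full occupancy."""
    r0 = (params.d0) / (params.a0 + params.beta * params.d0
                        + params.delta * params.a0)
    r1 = (params.d1) / (params.a1 + params.beta * params.d1
                        + params.delta * params.a0)
    return r1 / r0 - 1.0


@dataclass(frozen=True)
class TitrationFit:
    """Result of :func:`fit_titration`."""

    ec50: float            # binding EC50, gamma-corrected
    ec50_apparent: float   # midpoint of the ratio response itself
    hill: float
    r_unbound: float
    r_saturated: float
    gamma: float           # assumed relative acceptor change, (a1-a0)/a0
    residual_rms: float


def _logistic_ratio(c, ec50_app, n, r_u, r_s):
    x = (c / ec50_app) ** n
    return (r_u + r_s * x) / (1.0 + x)


def fit_titration(concentrations, ratios,
                  gamma: float | None = None) -> TitrationFit:
    """Recover binding parameters from a (concentration, ratio) titration.

    The two-state ratio model R(f) = (R_u + A f)/(1 + gamma f) with Hill
    occupancy f(c) reduces *exactly* to a 4-parameter logistic in c whose
    midpoint is EC50_app = EC50 * (1+gamma)^(-1/n), where gamma =
    (a1-a0)/a0 is the acceptor's relative change at saturation.  The ratio
    curve alone therefore cannot separate gamma from the binding EC50;
    ``gamma`` must be supplied as a known sensor constant (default: the
    value implied by the default emission coefficients, -1/6).  The fit is
    least squares on the logistic; the binding EC50 is then
    EC50_app * (1+gamma)^(1/n).

    Raises
    ------
    FitError
        If fewer than 5 distinct concentrations are given, the response is
        flat, or the optimizer fails; ``diagnostics`` explains why.
    """
    if gamma is None:
        defaults = SensorParams()
        gamma = (defaults.a1 - defaults.a0) / defaults.a0
    if not (-1.0 < gamma <= 0.0):
        raise ConfigError("gamma must lie in (-1, 0]")
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise ConfigError("concentrations and ratios must be 1-D and equal-length")
    if np.unique(c).size < 5:
        raise FitError("need >= 5 distinct concentrations",
                       {"n_distinct": int(np.unique(c).size)})
    if np.any(c < 0) or np.any(~np.isfinite(r)):
        raise ConfigError("concentrations must be >= 0 and ratios finite")

    span = float(np.ptp(r))
    if span <= 1e-9 * max(1.0, float(np.mean(np.abs(r)))):
        raise FitError("no response: all ratios are (near-)equal",
                       {"response_span": span})

    order = np.argsort(c)
    c_s, r_sorted = c[order], r[order]
    r_lo, r_hi = float(r_sorted[0]), float(r_sorted[-1])
    # initial EC50: first concentration past half response
    half = 0.5 * (r_lo + r_hi)
    above = np.nonzero(r_sorted >= half)[0]
    ec50_0 = float(c_s[above[0]]) if above.size else float(np.median(c_s[c_s > 0]))
    ec50_0 = max(ec50_0, float(np.min(c_s[c_s > 0])) if np.any(c_s > 0) else 1.0)
    p0 = [ec50_0, 2.0, r_lo, r_hi]
    lo = [1e-3, 0.2, 1e-6, 1e-6]
    hi = [1e9, 10.0, 1e6, 1e6]
    try:
        popt, _ = curve_fit(_logistic_ratio, c, r, p0=p0, bounds=(lo, hi),
                            x_scale=[max(ec50_0, 1.0), 1.0, 1.0, 1.0],
                            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"titration fit did not converge: {exc}",
                       {"p0": p0}) from exc
    ec50_app, n, r_u, r_s = (float(v) for v in popt)
    if not r_s > r_u:
        raise FitError("fitted response is not increasing",
                       {"r_unbound": r_u, "r_saturated": r_s})
    resid = r - _logistic_ratio(c, *popt)
    return TitrationFit(ec50=ec50_app * (1.0 + gamma) ** (1.0 / n),
                        ec50_apparent=ec50_app, hill=n,
                        r_unbound=r_u, r_saturated=r_s, gamma=float(gamma),
                        residual_rms=float(np.sqrt(np.mean(resid ** 2))))
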