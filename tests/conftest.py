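"""Shared phantom fixtures.

All imagery is generated at test time by the phantom module; nothing is
read from disk except in explicit I/O round-trip tests.
"""

import numpy as np
import pytest

import fretmask as fm

# ROI that contains the whole vessel (walls at every dilation state used
# in these tests) plus plenty of background
VESSEL_ROI = fm.RoiPolygon.rectangle(18, 8, 62, 56, "vessel")
# tight ROI: just inside the wall bands of the default static vessel
TIGHT_ROI = fm.RoiPolygon.rectangle(26, 20, 54, 44, "vessel")
BG_ROI = fm.RoiPolygon.rectangle(3, 4, 13, 20, "background")

SATURATING_PULSE = fm.Pulse(start_frame=15, c_max_nM=30000.0,
                            tau_on_s=0.1, tau_off_s=0.1, duration_s=200.0)


def noise_free(**kw) -> fm.PhantomConfig:
    base = dict(poisson_noise=False, read_noise_sigma=0.0,
                coupling=fm.Coupling(g_max=0.0), seed=1)
    base.update(kw)
    return fm.PhantomConfig(**base)


@pytest.fixture(scope="session")
def static_phantom():
    """Noise-free static vessel, no stimulus: every frame identical."""
    return fm.simulate_timelapse(noise_free(n_frames=10))


@pytest.fixture(scope="session")
def step_phantom():
    """Noise-free saturating cGMP step, no dilation."""
    cfg = noise_free(n_frames=40, pulses=(SATURATING_PULSE,))
    return fm.simulate_timelapse(cfg)


@pytest.fixture(scope="session")
def noisy_step_phantom():
    """Default-noise saturating cGMP step, no dilation."""
    cfg = fm.PhantomConfig(n_frames=80, pulses=(SATURATING_PULSE,),
                           coupling=fm.Coupling(g_max=0.0), seed=7)
    return fm.simulate_timelapse(cfg)


@pytest.fixture(scope="session")
def dilating_phantom():
    """Default-noise vessel with a cGMP pulse driving 30% dilation."""
    cfg = fm.PhantomConfig(
        n_frames=80, seed=11,
        pulses=(fm.Pulse(30, 5000.0, 10.0, 60.0, 120.0),),
        coupling=fm.Coupling(g_max=0.3, k_dil_nM=500.0, hill=2.0))
    return fm.simulate_timelapse(cfg)


@pytest.fixture(scope="session")
def saline_phantom():
    """Default-noise vessel dilating 30% with constant (zero) cGMP."""
    cfg = fm.PhantomConfig(
        n_frames=80, seed=5, dark_patches=((2, 2, 22, 14),),
        saline_bump=fm.SalineBump(35, 0.30, 150.0),
        coupling=fm.Coupling(g_max=0.0))
    return fm.simulate_timelapse(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
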