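import pytest

from prfbias.clf import CorticalMapping
from prfbias.phantom import HRFSpec
from prfbias.stimulus import make_bar_apertures


@pytest.fixture(scope="session")
def mapping():
    """V1-like cortical mapping (foveal magnification 14 mm/deg, E2 = 1.4 deg)."""
    return CorticalMapping(M0=14.0, E2=1.4)


@pytest.fixture(scope="session")
def small_stim():
    """Light bar-aperture design for unit tests: 4 sweeps of 8 steps at 32 px."""
    return make_bar_apertures(radius_deg=7.8, bar_width_deg=1.95, n_directions=4,
                              frames_per_sweep=8, resolution_px=32, tr_s=1.5)


@pytest.fixture(scope="session")
def small_hrf():
    return HRFSpec(tr_s=1.5)


@pytest.fixture(scope="session")
def run_stim():
    """Full 135-frame, 8-direction design at the desk-scale 24 px rendering."""
    return make_bar_apertures(radius_deg=7.8, bar_width_deg=1.95, n_directions=8,
                              frames_per_sweep=16, resolution_px=24, tr_s=1.883,
                              n_blank_frames=7)


@pytest.fixture(scope="session")
def run_hrf():
    return HRFSpec(tr_s=1.883)
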