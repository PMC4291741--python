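import numpy as np
import pytest

from owlrel.binaural import design_owl_gammatone_bank
from owlrel.hrtf import HeadModelParams, HRIRSet, generate_hrir_set


@pytest.fixture(scope="session")
def head_params():
    return HeadModelParams()


@pytest.fixture(scope="session")
def hrir_default(head_params):
    """The canonical (unjittered) synthetic owl head."""
    return generate_hrir_set(head_params, seed=1)


@pytest.fixture(scope="session")
def bank36():
    return design_owl_gammatone_bank()


@pytest.fixture(scope="session")
def bank_small():
    """5-channel bank for tests where rendering cost matters."""
    return design_owl_gammatone_bank(1000.0, 8000.0, 1750.0)


@pytest.fixture(scope="session")
def isotropic_params():
    """Delay-only head: no directional gain (frontal boost 0)."""
    return HeadModelParams(frontal_boost_db=0.0, axis_elevation_offset_deg=0.0)


@pytest.fixture(scope="session")
def hrir_isotropic(isotropic_params):
    return generate_hrir_set(isotropic_params, seed=2)


@pytest.fixture(scope="session")
def synthetic_reliability_map():
    """Hand-built reliability map with a clean diagonal ridge: the most
    reliable channel slides from ~7 kHz at the midline down to ~1.6 kHz
    at 90 deg azimuth (Gaussian profile, width 800 Hz)."""
    from owlrel.cues import ReliabilityMap

    az = np.arange(0.0, 91.0, 10.0)
    fcs = np.arange(1000.0, 8001.0, 200.0)
    ridge = 7000.0 - az * 60.0
    prof = 0.05 + np.exp(-((fcs[None, :] - ridge[:, None]) ** 2) / (2 * 800.0**2))
    prof = prof / prof.max(axis=1, keepdims=True)
    sd = 30.0 / np.sqrt(prof / prof.max())  # consistent circ-SD bookkeeping
    return ReliabilityMap(az, fcs, sd, prof, meta={"synthetic": True})


@pytest.fixture(scope="session")
def flat_reliability_map():
    """Uninformative map: every channel equally reliable everywhere."""
    from owlrel.cues import ReliabilityMap

    az = np.arange(0.0, 91.0, 10.0)
    fcs = np.arange(1000.0, 8001.0, 200.0)
    prof = np.ones((az.size, fcs.size))
    return ReliabilityMap(az, fcs, 10.0 * prof, prof, meta={"synthetic": True})


def make_impulse_hrir(
    scale_map=None,
    azimuths=np.arange(-160.0, 161.0, 20.0),
    elevations=np.arange(-40.0, 41.0, 10.0),
    fs=48000.0,
    n_taps=128,
    base=1e-3,
):
    """Hand-built HRIR set: a unit impulse at tap 0 per location, scaled
    per location by ``scale_map[(az, el)]`` (default ``base``)."""
    na, ne = azimuths.size, elevations.size
    left = np.zeros((na, ne, n_taps))
    right = np.zeros((na, ne, n_taps))
    for i, az in enumerate(azimuths):
        for j, el in enumerate(elevations):
            s = base if scale_map is None else scale_map.get((az, el), base)
            left[i, j, 0] = s
            right[i, j, 0] = s
    return HRIRSet(azimuths, elevations, fs, left, right)
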