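import numpy as np
import pytest

from fipcouple import PhotometrySession, SimParams, simulate_session


@pytest.fixture
def fs() -> float:
    return 40.0


@pytest.fixture
def smooth_pair(fs):
    """Identical smooth trace pair (10 s at 40 Hz) for correlation tests."""
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(42)
    a = gaussian_filter1d(rng.standard_normal(400), 4.0)
    return a.copy(), a.copy()


@pytest.fixture
def flat_session(fs):
    """Constant-fluorescence session: dF/F0 must be identically zero."""
    n = 40 * 30
    t = np.arange(n) / fs
    return PhotometrySession(
        time=t, channels={"sig": np.full(n, 10.0)}, sampling_rate=fs
    )


@pytest.fixture(scope="session")
def default_session():
    """One noiseless-lag-free synthetic session, shared across tests."""
    params = SimParams(session_length=200.0, n_events={"digging": 5},
                       noise_sd=0.0, bleach_amplitude=0.0,
                       motion_artifact_sd=0.0, seed=7)
    return simulate_session(params)
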