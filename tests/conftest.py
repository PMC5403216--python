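import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import replikinetics as rk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def spt_settings():
    """500 ms exposures spaced by 1 s intervals (fast-turnover protocol)."""
    return rk.AcquisitionSettings(exposure_time=0.5, interval_time=1.0, n_frames=600)


@pytest.fixture
def continuous_settings():
    """Continuous 500 ms illumination (bleach-control / blink protocol)."""
    return rk.AcquisitionSettings(exposure_time=0.5, interval_time=0.5, n_frames=600)


@pytest.fixture
def bleach_calibration(continuous_settings):
    """Calibration from a large simulated stable-binder control."""
    params = rk.TrackSimParams(true_bound_time=np.inf,
                               constant_exposure_bleach_time=15.0,
                               n_molecules=4000, seed=1234)
    control = rk.gen_bleach_control(params, continuous_settings, min_localizations=4)
    return rk.calibrate_bleach(control)


def make_track(frames, x=0.0, y=0.0, sigma_x=100.0, sigma_y=110.0,
               intensity=1000.0, track_id=0):
    """Build a Track with constant per-localization attributes."""
    frames = np.asarray(frames, dtype=int)
    n = frames.size
    return rk.Track(
        track_id=track_id,
        frames=frames,
        x=np.full(n, float(x)),
        y=np.full(n, float(y)),
        sigma_x=np.full(n, float(sigma_x)),
        sigma_y=np.full(n, float(sigma_y)),
        intensity=np.full(n, float(intensity)),
        localization_indices=np.arange(n),
    )
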