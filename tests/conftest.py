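import numpy as np
import pytest

import devconn as dc
from devconn.containers import ParcelTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    return dc.generate_cohort(30, age_range=(6.0, 45.0), sex_ratio=0.5, seed=11)


@pytest.fixture
def sinusoid_ts():
    """Three parcels: 10 Hz, 10 Hz lagged by pi/4, and 25 Hz, one 10-s trial."""
    fs = 600.0
    t = np.arange(int(10 * fs)) / fs
    data = np.stack(
        [
            np.cos(2 * np.pi * 10 * t),
            np.cos(2 * np.pi * 10 * t - np.pi / 4),
            np.cos(2 * np.pi * 25 * t),
        ]
    )[np.newaxis]
    return ParcelTimeSeries(subject_id="sin", data=data, sampling_rate_hz=fs)


@pytest.fixture
def noise_ts(rng):
    """Five parcels of white noise, 4 trials, 5 s at 300 Hz."""
    data = rng.standard_normal((4, 5, 1500))
    return ParcelTimeSeries(subject_id="noise", data=data, sampling_rate_hz=300.0)
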