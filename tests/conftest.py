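"""Shared fixtures: small seeded recordings and cohorts."""

import numpy as np
import pytest

from doceeg import synthetic
from doceeg.recording import EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_pair():
    """Two channels of independent white noise, 60 s at 250 Hz (59 epochs)."""
    r = np.random.default_rng(0)
    return EEGRecording(r.standard_normal((2, 15000)), fs=250.0)


@pytest.fixture
def lagged_alpha_pair():
    """Shared alpha-band source reaching channel 2 with a 90-degree lag."""
    src = synthetic._band_limited_noise(np.random.default_rng(7), 15000, 250.0,
                                        8.0, 13.0)
    pair = synthetic._phase_shift(src, np.array([0.0, np.pi / 2]), 15000)
    return EEGRecording(pair, fs=250.0)


@pytest.fixture
def small_cohort():
    return synthetic.generate_cohort(seed=42)


@pytest.fixture
def profiles():
    return synthetic.default_profiles()
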