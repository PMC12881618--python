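import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_protocol():
    """A short, low-rate protocol for tests that only need the shape of a cycle."""
    from spiralpam import ScanProtocol

    return ScanProtocol(
        scan_frequency=100.0,
        imaging_duration=0.2,
        braking_duration=0.05,
        decay_duration=0.05,
        max_radius=1e-3,
    )


def gabor_pulse(carrier_hz, sigma_t, sampling_rate, n_samples, center_index=None):
    """Gaussian-envelope tone burst sampled at ``sampling_rate``."""
    t = np.arange(n_samples) / sampling_rate
    if center_index is None:
        center_index = n_samples // 2
    t0 = center_index / sampling_rate
    return np.exp(-((t - t0) ** 2) / (2 * sigma_t**2)) * np.cos(
        2 * np.pi * carrier_hz * (t - t0)
    )
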