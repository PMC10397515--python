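import numpy as np
import pytest

from tonicquant import CurrentTrace, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """A short, noiseless, event-free recording configuration."""
    return SimConfig(
        duration_s=2.0, noise_sd_pa=0.0, event_rate_hz=0.0,
        tonic_shift_pa=0.0, seed=0,
    )


@pytest.fixture
def gaussian_trace(rng):
    """5 s of pure Gaussian noise around -50 pA (no events, no drug)."""
    samples = rng.normal(-50.0, 3.0, size=50_000)
    return CurrentTrace(samples=samples, sampling_rate_hz=10_000.0)


def make_drug_trace(**overrides):
    """A standard drug-application recording config for pipeline tests."""
    defaults = dict(
        duration_s=175.0, t_drug_s=30.0, i_hold_pa=-50.0,
        noise_sd_pa=3.0, event_rate_hz=2.0, tonic_shift_pa=22.5, seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
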