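import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import odortrace as ot
from odortrace.substances import default_library

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture
def noiseless_gc():
    """GC-coupled acquisition with all noise sources off."""
    return ot.AcquisitionSpec.gc_coupled(noise_sd=0.0, fid_noise_sd=0.0)


@pytest.fixture
def flat_bleach_gc():
    """Noise-free GC acquisition with no bleaching (flat baseline)."""
    return ot.AcquisitionSpec.gc_coupled(
        noise_sd=0.0, fid_noise_sd=0.0, bleach=(0.0, 300.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def to_dff(trial_or_trace, f0=1000.0):
    """Convert a flat-bleach raw fluorescence trace to exact dF/F."""
    trace = trial_or_trace
    return trace.with_values(trace.values / f0 - 1.0, channel="dff")


@pytest.fixture
def make_dff():
    return to_dff
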