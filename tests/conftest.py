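import numpy as np
import pytest
from hypothesis import settings

from polyphos.signal_io import Trace
from polyphos.species_db import default_database

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def db():
    return default_database()


@pytest.fixture
def make_trace():
    """Factory: Gaussian peaks (rt, height, sigma) on an offset, optional noise."""

    def _make(peaks, offset=5.0, noise_sd=0.0, drift=0.0, t0=0.0, t1=30.0, dt=0.005, seed=0):
        t = np.arange(t0, t1 + dt / 2, dt)
        y = np.full_like(t, float(offset)) + drift * (t - t0)
        for rt, h, sig in peaks:
            y += h * np.exp(-0.5 * ((t - rt) / sig) ** 2)
        if noise_sd > 0:
            y += np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
        return Trace(channel="SCD", times=t, intensities=y)

    return _make
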