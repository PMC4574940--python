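import numpy as np
import pytest

import meegconnet as m


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def graphs():
    return m.fixture_graphs()


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    y = 1 - 2 * i / (n - 1)
    r = np.sqrt(np.maximum(0, 1 - y * y))
    return np.c_[r * np.cos(phi * i), y, r * np.sin(phi * i)]


@pytest.fixture
def sensor_layout():
    return m.ChannelLayout([f"e{i}" for i in range(32)], fibonacci_sphere(32))


@pytest.fixture
def noise_recording(rng):
    """4 channels x 600 samples x 3 trials of white noise at 200 Hz."""
    return m.Recording(
        rng.normal(size=(4, 600, 3)), sfreq=200.0,
        channel_labels=list("abcd"),
    )


def lagged_sine_recording(freq=10.0, sfreq=200.0, n=2000, lag=np.pi / 4):
    """Two equal-frequency sinusoids with a fixed phase lag plus a third
    independent noisy channel is NOT included: just the locked pair."""
    t = np.arange(n) / sfreq
    x = np.vstack([
        np.sin(2 * np.pi * freq * t),
        np.sin(2 * np.pi * freq * t + lag),
    ])
    return m.Recording(x, sfreq=sfreq, channel_labels=["x", "y"])
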