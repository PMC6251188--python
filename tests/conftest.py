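import logging

import numpy as np
import pytest

from fibwave.movie_io import RunConfig, VoltageMovie

logging.getLogger("fibwave").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def small_movie(rng):
    """10-frame 8x8 random movie."""
    return VoltageMovie(rng.random((10, 8, 8)), dt=1.0, pitch=0.44)


@pytest.fixture
def sine_movie():
    """10 Hz sinusoid at every pixel, 3 s at 1 kHz, 8x8 grid."""
    t = np.arange(3000) / 1000.0
    trace = np.sin(2 * np.pi * 10.0 * t)
    data = np.tile(trace[:, None, None], (1, 8, 8))
    return VoltageMovie(data, dt=1.0, pitch=0.44)


def disc_mask(shape, center=None, radius=None):
    h, w = shape
    if center is None:
        center = (h // 2, w // 2)
    if radius is None:
        radius = min(h, w) // 2 - 2
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    return np.hypot(rr - center[0], cc - center[1]) <= radius
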