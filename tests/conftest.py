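import numpy as np
import pytest

from preyflow import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_trials():
    """Default crossover design: 24 groups x 4 treatments, 5 exclusions."""
    return synthetic.design_crossover(master_seed=0)


@pytest.fixture(scope="session")
def default_metadata(default_trials):
    return synthetic.metadata_frame(default_trials)


def make_smooth_texture(n=96, period=24):
    """Smooth sinusoidal plaid with strong gradients everywhere, values in [0,1]."""
    x = np.arange(n)
    X, Y = np.meshgrid(x, x)
    return 0.5 + 0.22 * np.sin(2 * np.pi * X / period) + 0.22 * np.sin(2 * np.pi * Y / period + 1.0)


def subpixel_shift_cols(img, dx):
    """Circular shift along columns by a (possibly fractional) dx via FFT."""
    k = np.fft.fftfreq(img.shape[1])
    ramp = np.exp(-2j * np.pi * k * dx)[None, :]
    return np.real(np.fft.ifft(np.fft.fft(img, axis=1) * ramp, axis=1))
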