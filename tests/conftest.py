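import numpy as np
import pytest

from epihybrid import SynthConfig, TrainConfig, generate_frames
from epihybrid.train import train_pipeline


def dft_oracle(x: np.ndarray) -> np.ndarray:
    """O(n^2) direct DFT in double precision: the independent reference for
    the radix-2 FFT."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    k = np.arange(n)
    M = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return x @ M.T


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_frames():
    """160 labeled synthetic frames, balanced classes."""
    return generate_frames(SynthConfig(seed=3, n_frames=160))


@pytest.fixture(scope="session")
def trained(small_frames):
    """A quickly trained pipeline shared by inference-level tests."""
    return train_pipeline(small_frames, TrainConfig(seed=3, epochs=6))
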