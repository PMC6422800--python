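import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from eegmst import CouplingSpec, MultichannelRecording, gen_coupled_signals


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quadrature_pair() -> MultichannelRecording:
    """Two channels coupled at a constant pi/2 lag, no noise."""
    spec = CouplingSpec(n_channels=2, band="theta",
                        edges=[(0, 1, np.pi / 2, 1.0)],
                        noise_sd=0.0, seed=3)
    return gen_coupled_signals(spec, duration_s=10.0, fs=250.0)


@pytest.fixture
def noise_recording() -> MultichannelRecording:
    """Eight noise-only channels (independent 1/f noise, no oscillator)."""
    spec = CouplingSpec(n_channels=8, band="gamma", edges=[],
                        noise_sd=2.0, amplitude=0.0, seed=4)
    return gen_coupled_signals(spec, duration_s=30.0, fs=128.0)


def sine_recording(freq: float, fs: float = 500.0, duration: float = 10.0,
                   amplitude: float = 1.0) -> MultichannelRecording:
    t = np.arange(round(duration * fs)) / fs
    return MultichannelRecording(amplitude * np.sin(2 * np.pi * freq * t)[None, :],
                                 ["ch00"], fs)
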