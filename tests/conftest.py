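import numpy as np
import pytest

from freqhar.benchmark import run_benchmark_trial
from freqhar.spectral import SpectrumGrid

PIPELINE_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def benchmark_trials():
    """Full three-phase pipeline on the synthetic benchmark, three seeds.

    Computed once per session: the trials feed the planted-frequency
    recovery check, the ablation-ordering check and the window-shape
    comparison.
    """
    return [run_benchmark_trial(seed) for seed in PIPELINE_SEEDS]


@pytest.fixture
def grid256():
    """The classic 256-sample window at 100 Hz (bin width 0.390625 Hz)."""
    return SpectrumGrid(256, 100.0)


@pytest.fixture
def grid32():
    return SpectrumGrid(32, 32.0)


def make_tone(w: int, k: int, amplitude: float = 1.0, phase: float = 0.0):
    """Unit tone exactly on bin k of a length-w window."""
    t = np.arange(w)
    return amplitude * np.cos(2 * np.pi * k * t / w + phase)


def tone_amplitude(x: np.ndarray, k: int) -> float:
    """Amplitude of the bin-k component via the DFT magnitude."""
    w = len(x)
    mag = np.abs(np.fft.rfft(x)[k])
    if k == 0 or (w % 2 == 0 and k == w // 2):
        return mag / w
    return 2 * mag / w
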