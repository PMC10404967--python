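import numpy as np
import pytest

from hiset import signal_io_synth as sio


@pytest.fixture(scope="session")
def small_dataset():
    """36-cycle three-class synthetic dataset at desk scale."""
    cfg = sio.SynthConfig(
        n_per_class=12,
        duration_s=0.8,
        sample_rate=2000.0,
        snr_db=10.0,
        wheeze_freq_range=(100.0, 600.0),
        seed=7,
    )
    return sio.synthesize_dataset(cfg, sio.THREE_CLASS)


@pytest.fixture()
def two_tone():
    fs = 1000.0
    t = np.arange(1000) / fs
    return np.sin(2 * np.pi * 5 * t) + 0.5 * np.sin(2 * np.pi * 50 * t), fs


def tone_sum(freqs, fs=1000.0, n=1000, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    return sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) for f in freqs)


def dominant_frequency(x, fs):
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return freqs[np.argmax(spec)]
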