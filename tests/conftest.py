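import numpy as np
import pytest

from fpvs.data_model import StimulusProtocol
from fpvs.spectral import AmplitudeSpectrum
from fpvs.synth import SimulationConfig


@pytest.fixture
def protocol():
    return StimulusProtocol()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectrum(amps, fs=512.0, n_samples=None, source_class="LF"):
    """Wrap a raw amplitude vector (one value per rfft bin)."""
    amps = np.asarray(amps, dtype=float)
    if n_samples is None:
        n_samples = 2 * (len(amps) - 1)
    freqs = np.arange(len(amps)) * fs / n_samples
    return AmplitudeSpectrum(frequencies=freqs, amplitudes=amps,
                             bin_resolution=fs / n_samples,
                             n_samples=n_samples, fs=fs,
                             source_class=source_class)


@pytest.fixture
def quiet_config():
    """Noise-free, carrier-free configuration: only phase-locked terms."""
    return SimulationConfig(noise_scale=0.0, hf_carrier_scale=0.0,
                            sequence_jitter_sd=0.0, n_sequences=1)
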