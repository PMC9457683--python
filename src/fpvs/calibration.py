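"""Null calibration of the harmonic-summed Z statistic.

Pushes large numbers of no-signal (noise-only) contacts through the LF
and HF pipelines in vectorised chunks to measure the false-positive rate
of the Z > 3.1 criterion. The chunked code applies exactly the same
operations as the scalar pipeline (1/f noise synthesis, time-domain
averaging, integer-cycle cropping, FFT, segment summing, surround
standardisation); scalar/batch equivalence is covered by the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.fft

from .envelope import HFConfig, envelope_usable_segment, hf_envelope_batch
from .spectral import crop_integer_cycles
from .synth import SimulationConfig


def _noise_batch(n_traces: int, n_samples: int, fs: float, exponent: float,
                 rms: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorised 1/f noise: (n_traces, n_samples), each with target RMS."""
    n_bins = n_samples // 2 + 1
    freqs = scipy.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros(n_bins)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_traces, n_bins))
            + 1j * rng.standard_normal((n_traces, n_bins))) * shape
    x = scipy.fft.irfft(spec, n=n_samples, axis=-1)
    x *= rms / np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x


def zscore_face_rows(amps: np.ndarray, n_samples: int, fs: float,
                     face_rate: float = 1.2, n_harmonics: int = 4,
                     n_side: int = 25) -> np.ndarray:
    """Harmonic-summed Z for each row of a batch of amplitude spectra."""
    seg = np.zeros(amps.shape[:-1] + (2 * n_side + 1,))
    for h in range(1, n_harmonics + 1):
        k = int(round(h * face_rate * n_samples / fs))
        seg += amps[..., k - n_side:k + n_side + 1]
    center = seg[..., n_side]
    surround = np.delete(seg, [n_side - 1, n_side, n_side + 1], axis=-1)
    mu = surround.mean(axis=-1)
    sd = surround.std(axis=-1)
    return (center - mu) / sd


def _spectra_rows(traces: np.ndarray) -> np.ndarray:
    n = traces.shape[-1]
    amps = np.abs(scipy.fft.rfft(traces, axis=-1)) * 2.0 / n
    amps[..., 0] /= 2.0
    return amps


def null_z_lf(n_contacts: int, config: SimulationConfig, seed: int,
              chunk: int = 256) -> np.ndarray:
    """Z of noise-only contacts through the LF pipeline."""
    rng = np.random.default_rng(seed)
    proto = config.protocol
    fs = config.fs
    n_usable = int(round(proto.usable_duration * fs))
    zs = []
    done = 0
    while done < n_contacts:
        m = min(chunk, n_contacts - done)
        traces = _noise_batch(m * config.n_sequences, n_usable, fs,
                              config.noise_exponent, config.noise_scale,
                              rng)
        mean_traces = traces.reshape(m, config.n_sequences, -1).mean(axis=1)
        cropped, _ = crop_integer_cycles(mean_traces, fs, proto)
        amps = _spectra_rows(cropped)
        zs.append(zscore_face_rows(amps, cropped.shape[-1], fs,
                                   proto.face_rate))
        done += m
    return np.concatenate(zs)


def null_z_hf(n_contacts: int, config: SimulationConfig, seed: int,
              hf_config: HFConfig = HFConfig(),
              chunk: int = 64) -> np.ndarray:
    """Z of noise-only contacts through the HF envelope pipeline."""
    rng = np.random.default_rng(seed)
    proto = config.protocol
    fs = config.fs
    n_total = int(round((config.pre_s + proto.sequence_duration
                         + config.post_s) * fs))
    onset_sample = int(round(config.pre_s * fs))
    zs = []
    done = 0
    # chunk counts traces, not contacts: envelope intermediates are
    # (traces x 41 freqs x samples) and must stay comfortably in memory
    contacts_per_chunk = max(1, chunk // config.n_sequences)
    while done < n_contacts:
        m = min(contacts_per_chunk, n_contacts - done)
        traces = _noise_batch(m * config.n_sequences, n_total, fs,
                              config.noise_exponent, config.noise_scale,
                              rng)
        env = hf_envelope_batch(traces, fs, hf_config, onset_sample)
        usable = envelope_usable_segment(env, proto)
        cropped, _ = crop_integer_cycles(usable, env.fs_env, proto)
        mean_env = cropped.reshape(m, config.n_sequences, -1).mean(axis=1)
        amps = _spectra_rows(mean_env)
        zs.append(zscore_face_rows(amps, mean_env.shape[-1], env.fs_env,
                                   proto.face_rate))
        done += m
    return np.concatenate(zs)
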