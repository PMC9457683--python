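"""Frequency-domain quantification of frequency-tagged responses.

The same machinery serves both signal classes: the low-frequency (LF)
phase-locked response is quantified from the FFT of the time-averaged raw
trace, and the high-frequency broadband (HF) response from the FFT of the
time-averaged 40-160 Hz amplitude envelope.

Key statistic: the harmonic-summed Z-score. The amplitude spectrum is cut
into four segments centred on the face frequency (1.2 Hz) and its first
harmonics (2.4, 3.6, 4.8 Hz), each with 25 neighbouring bins per side; the
segments are summed elementwise and the centre bin is standardised against
the 48 surrounding bins (25 per side minus the 2 bins adjacent to the
centre). Z > 3.1 (one-tailed p < 0.001) marks a face-selective contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .data_model import StimulusProtocol

#: Face-selective harmonics used for amplitude quantification: the first
#: 14 harmonics of 1.2 Hz minus the 5th and 10th (6 and 12 Hz), which
#: coincide with the base stimulation frequency.
FACE_HARMONICS = tuple(
    round(1.2 * k, 1) for k in range(1, 15) if k not in (5, 10))

#: Base-rate harmonics used for the general visual response (6-18 Hz).
BASE_HARMONICS = (6.0, 12.0, 18.0)

#: Default significance threshold on the harmonic-summed Z.
Z_THRESHOLD = 3.1


class UndefinedZError(ValueError):
    """Surround standard deviation is zero; Z is undefined."""


class TooShortError(ValueError):
    """Usable analysis window holds less than one face cycle."""


@dataclass
class AmplitudeSpectrum:
    """Single-sided FFT amplitude spectrum for one contact/signal class.

    Amplitudes use the 2/N convention: a unit-amplitude cosine sitting on
    an exact bin yields amplitude 1 at that bin. Units are uV for the LF
    signal and percent signal change for the HF envelope.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    bin_resolution: float
    n_samples: int
    fs: float
    source_class: str = "LF"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.frequencies.shape != self.amplitudes.shape:
            raise ValueError("frequency/amplitude shape mismatch")

    def bin_index(self, f: float) -> int:
        """Index of the bin nearest frequency ``f`` (round(f*N/fs))."""
        k = int(round(f * self.n_samples / self.fs))
        if not 0 <= k < len(self.amplitudes):
            raise ValueError(f"{f} Hz outside spectrum")
        return k


@dataclass
class HarmonicQuant:
    """Per-contact, per-signal-class harmonic quantification."""

    z_face: float
    face_amp: float
    base_amp: float
    signal_index: float = np.nan
    noise_index: float = np.nan
    classification: str = ""


def crop_integer_cycles(trace: np.ndarray, fs: float,
                        protocol: StimulusProtocol) -> tuple[np.ndarray, int]:
    """Crop a usable-window trace to an integer number of face cycles.

    ``trace`` must start at ``protocol.analysis_start`` (end of fade-in).
    Retains the largest integer number K of face cycles that fit within
    the usable window (70 s protocol: 66 s -> K = 79, 65.83 s), over
    N = round(K * fs / face_rate) samples, which puts the face frequency
    exactly on FFT bin K up to one-sample rounding.

    Returns ``(cropped_trace, K)``.
    """
    trace = np.asarray(trace, dtype=float)
    face_rate = protocol.face_rate
    usable_s = min(trace.shape[-1] / fs, protocol.usable_duration)
    # guard against float droop: 66*1.2 = 79.2 must not round down to 78
    n_cycles = int(np.floor(usable_s * face_rate + 1e-9))
    if n_cycles < 1:
        raise TooShortError("usable window shorter than one face cycle")
    n_samples = int(round(n_cycles * fs / face_rate))
    if n_samples > trace.shape[-1]:  # rounding overshoot by one sample
        n_samples = trace.shape[-1]
    return trace[..., :n_samples], n_cycles


def amplitude_spectrum(trace: np.ndarray, fs: float,
                       source_class: str = "LF") -> AmplitudeSpectrum:
    """Single-sided FFT amplitude spectrum of one (averaged) trace."""
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    amps = np.abs(scipy.fft.rfft(trace)) * 2.0 / n
    amps[0] /= 2.0  # DC is not doubled
    freqs = scipy.fft.rfftfreq(n, d=1.0 / fs)
    return AmplitudeSpectrum(
        frequencies=freqs, amplitudes=amps, bin_resolution=fs / n,
        n_samples=n, fs=fs, source_class=source_class)


def lf_spectrum(sequences: list[np.ndarray], fs: float,
                source_class: str = "LF") -> AmplitudeSpectrum:
    """Average cropped sequences in the time domain, then FFT.

    Time-domain averaging preserves the phase-locked response while
    non-phase-locked activity cancels as ~1/sqrt(S).
    """
    if len(sequences) == 0:
        raise ValueError("no sequences to average")
    lengths = {np.shape(s)[-1] for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences differ in length")
    mean_trace = np.mean(np.asarray(sequences, dtype=float), axis=0)
    return amplitude_spectrum(mean_trace, fs, source_class=source_class)


def _summed_harmonic_segment(spectrum: AmplitudeSpectrum,
                             face_rate: float = 1.2, n_harmonics: int = 4,
                             n_side: int = 25) -> np.ndarray:
    segs = []
    for h in range(1, n_harmonics + 1):
        k = spectrum.bin_index(h * face_rate)
        if k - n_side < 0 or k + n_side >= len(spectrum.amplitudes):
            raise ValueError(
                f"spectrum too short for +-{n_side} bins around harmonic "
                f"{h} ({h * face_rate} Hz)")
        segs.append(spectrum.amplitudes[k - n_side:k + n_side + 1])
    return np.sum(segs, axis=0)


def zscore_face(spectrum: AmplitudeSpectrum, face_rate: float = 1.2,
                n_harmonics: int = 4, n_side: int = 25,
                ddof: int = 0) -> float:
    """Harmonic-summed Z-score of the face-selective response.

    Population (n-denominator) standard deviation by default; set
    ``ddof=1`` for the sample convention.
    """
    seg = _summed_harmonic_segment(spectrum, face_rate, n_harmonics, n_side)
    center = n_side
    surround = np.delete(seg, [center - 1, center, center + 1])
    sd = float(np.std(surround, ddof=ddof))
    if sd == 0:
        raise UndefinedZError("zero surround standard deviation")
    return float((seg[center] - surround.mean()) / sd)


def baseline_subtracted_amplitude(spectrum: AmplitudeSpectrum, f: float,
                                  n_side: int = 25,
                                  min_side: int = 10) -> float:
    """Bin amplitude at ``f`` minus its local surround mean.

    The surround is up to 25 bins per side, excluding the bin adjacent to
    the target on each side; truncated at spectrum edges but never below
    ``min_side`` bins per side. Removes the 1/f spectral floor so that
    amplitudes are comparable across frequencies.
    """
    k = spectrum.bin_index(f)
    amps = spectrum.amplitudes
    lo = max(0, k - n_side)
    hi = min(len(amps), k + n_side + 1)
    if k - lo < min_side + 1 or hi - k - 1 < min_side + 1:
        raise ValueError(
            f"fewer than {min_side} surround bins per side at {f} Hz")
    surround = np.concatenate([amps[lo:k - 1], amps[k + 2:hi]])
    return float(amps[k] - surround.mean())


def face_selective_amplitude(spectrum: AmplitudeSpectrum,
                             harmonics=FACE_HARMONICS) -> float:
    """Summed baseline-subtracted amplitude over the 12 face harmonics."""
    return float(sum(baseline_subtracted_amplitude(spectrum, f)
                     for f in harmonics))


def base_amplitude(spectrum: AmplitudeSpectrum,
                   harmonics=BASE_HARMONICS) -> float:
    """Summed baseline-subtracted amplitude at 6, 12 and 18 Hz."""
    return float(sum(baseline_subtracted_amplitude(spectrum, f)
                     for f in harmonics))


def classify_contact(z_lf: float, z_hf: float,
                     threshold: float = Z_THRESHOLD) -> str:
    """Four-way contact classification by independent thresholding."""
    lf = z_lf > threshold
    hf = z_hf > threshold
    if lf and hf:
        return "LF+HF+"
    if lf:
        return "LF+HF-"
    if hf:
        return "LF-HF+"
    return "ns"


def signal_noise_indices(spectrum: AmplitudeSpectrum, face_rate: float = 1.2,
                         n_harmonics: int = 4, n_side: int = 25
                         ) -> tuple[float, float]:
    """Scale-invariant decomposition of the Z-score into signal and noise.

    Each scored harmonic bin is normalised by its local surround mean,
    removing the 1/f trend: the signal index is the summed fractional
    elevation of the harmonic bins above their surrounds, and the noise
    index is the mean coefficient of variation (sd/mean) of the surrounds.
    Both are invariant to rescaling the whole spectrum.
    """
    amps = spectrum.amplitudes
    signal = 0.0
    cvs = []
    for h in range(1, n_harmonics + 1):
        k = spectrum.bin_index(h * face_rate)
        lo, hi = k - n_side, k + n_side + 1
        if lo < 0 or hi > len(amps):
            raise ValueError("spectrum too short for surround window")
        surround = np.concatenate([amps[lo:k - 1], amps[k + 2:hi]])
        mu = surround.mean()
        if mu <= 0:
            raise ValueError("non-positive surround mean; indices undefined")
        signal += amps[k] / mu - 1.0
        cvs.append(np.std(surround) / mu)
    return float(signal), float(np.mean(cvs))


def quantify_spectrum(spectrum: AmplitudeSpectrum,
                      with_indices: bool = True) -> HarmonicQuant:
    """Full per-contact quantification of one amplitude spectrum."""
    q = HarmonicQuant(
        z_face=zscore_face(spectrum),
        face_amp=face_selective_amplitude(spectrum),
        base_amp=base_amplitude(spectrum),
    )
    if with_indices:
        q.signal_index, q.noise_index = signal_noise_indices(spectrum)
    return q
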