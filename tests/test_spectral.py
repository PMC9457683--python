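"""Cropping, averaged-spectrum estimation and harmonic quantification."""

import numpy as np
import pytest

from conftest import make_spectrum
from fpvs.data_model import StimulusProtocol
from fpvs.spectral import (BASE_HARMONICS, FACE_HARMONICS, TooShortError,
                           UndefinedZError, base_amplitude,
                           baseline_subtracted_amplitude, classify_contact,
                           crop_integer_cycles, face_selective_amplitude,
                           lf_spectrum, amplitude_spectrum,
                           signal_noise_indices, zscore_face)


class TestCropIntegerCycles:
    def test_protocol_window_gives_79_cycles(self, protocol):
        trace = np.zeros(int(66 * 512))
        cropped, k = crop_integer_cycles(trace, 512.0, protocol)
        assert k == 79
        assert len(cropped) == 33707  # round(79 * 512 / 1.2)
        assert len(cropped) / 512.0 == pytest.approx(65.83, abs=0.005)

    def test_exact_cycles_kept(self):
        proto = StimulusProtocol(sequence_duration=10 / 1.2 + 0.2,
                                 analysis_start=0.0, fade_in=0.1,
                                 fade_out=0.2)
        trace = np.zeros(int(round(10 / 1.2 * 500)))
        cropped, k = crop_integer_cycles(trace, 500.0, proto)
        assert k == 10
        assert len(cropped) == len(trace)

    def test_face_bin_lands_on_cycle_count(self, protocol):
        trace = np.zeros(int(66 * 512))
        cropped, k = crop_integer_cycles(trace, 512.0, protocol)
        n = len(cropped)
        assert round(1.2 * n / 512.0) == k == 79

    def test_window_below_one_cycle_rejected(self, protocol):
        with pytest.raises(TooShortError):
            crop_integer_cycles(np.zeros(100), 512.0, protocol)


class TestLFSpectrum:
    def test_dc_input_has_no_nonzero_bins(self):
        spec = lf_spectrum([np.full(1000, 3.0)], 500.0)
        assert np.allclose(spec.amplitudes[1:], 0.0, atol=1e-12)
        assert spec.amplitudes[0] == pytest.approx(3.0)

    def test_opposite_phases_cancel(self):
        t = np.arange(1000) / 500.0
        s = np.cos(2 * np.pi * 10 * t)
        spec = lf_spectrum([s, -s], 500.0)
        assert spec.amplitudes[spec.bin_index(10.0)] < 1e-12

    def test_unit_cosine_amplitude_convention(self):
        # integer number of cycles -> amplitude a at the bin within 1%
        a, f, fs = 2.5, 1.2, 512.0
        n = round(79 * fs / 1.2)
        t = np.arange(n) / fs
        spec = lf_spectrum([a * np.cos(2 * np.pi * f * t)], fs)
        assert spec.amplitudes[spec.bin_index(f)] == pytest.approx(
            a, rel=0.01)

    def test_sequence_order_invariance(self, rng):
        seqs = list(rng.standard_normal((4, 800)))
        s1 = lf_spectrum(seqs, 500.0).amplitudes
        s2 = lf_spectrum(seqs[::-1], 500.0).amplitudes
        assert np.allclose(s1, s2)

    def test_averaging_reduces_noise_like_sqrt_s(self, rng):
        """Across-sequence averaging shrinks the face-bin noise ~1/sqrt(S)."""
        fs = 500.0
        n = int(round(36 * 500 / 1.2))  # 36 face cycles
        levels = {}
        for s_count in (2, 8, 32):
            amps = []
            for _ in range(40):
                seqs = rng.standard_normal((s_count, n))
                spec = lf_spectrum(list(seqs), fs)
                amps.append(spec.amplitudes[spec.bin_index(1.2)])
            levels[s_count] = np.mean(amps)
        assert levels[2] / levels[8] == pytest.approx(2.0, rel=0.2)
        assert levels[8] / levels[32] == pytest.approx(2.0, rel=0.2)


def constructed_z_spectrum(center=11.0, hi=3.0, lo=-1.0, fs=512.0,
                           k_face=79):
    """Spectrum whose summed 4-harmonic segment has a known Z.

    Harmonic 1 segment carries the payload; harmonics 2-4 segments are
    zero. Surround: 24 bins at ``hi`` and 24 at ``lo``.
    """
    n_samples = int(round(k_face * fs / 1.2))
    n_bins = n_samples // 2 + 1
    amps = np.zeros(n_bins)
    seg = np.empty(51)
    surround_vals = np.array([hi, lo] * 24)
    j = 0
    for i in range(51):
        if i == 25:
            seg[i] = center
        elif i in (24, 26):
            seg[i] = 0.0  # excluded adjacent bins
        else:
            seg[i] = surround_vals[j]
            j += 1
    amps[k_face - 25:k_face + 26] = seg
    return make_spectrum(amps, fs=fs, n_samples=n_samples)


class TestZScore:
    def test_flat_segment_gives_zero(self):
        spec = constructed_z_spectrum(center=1.0, hi=1.0, lo=1.0)
        with pytest.raises(UndefinedZError):
            zscore_face(spec)  # sd 0 -> undefined, flagged

    def test_constructed_value(self):
        # center 11, surround mean 1, population sd 2 -> Z = 5
        spec = constructed_z_spectrum(center=11.0, hi=3.0, lo=-1.0)
        assert zscore_face(spec) == pytest.approx(5.0)

    def test_threshold_is_strict_at_3_1(self):
        assert classify_contact(3.2, 0.0) == "LF+HF-"
        assert classify_contact(3.0, 0.0) == "ns"
        assert classify_contact(3.1, 3.1) == "ns"

    def test_matches_brute_force_on_random_spectra(self, rng):
        """Oracle: naive loop over segments and surround bins."""
        for _ in range(200):
            fs = 512.0
            n_samples = int(round(79 * fs / 1.2))
            n_bins = n_samples // 2 + 1
            amps = rng.gamma(2.0, 1.0, n_bins)
            spec = make_spectrum(amps, fs=fs, n_samples=n_samples)

            seg = np.zeros(51)
            for h in (1, 2, 3, 4):
                k = round(h * 1.2 * n_samples / fs)
                seg += amps[k - 25:k + 26]
            surround = [seg[i] for i in range(51) if i not in (24, 25, 26)]
            expected = (seg[25] - np.mean(surround)) / np.std(surround)
            assert zscore_face(spec) == pytest.approx(expected)


class TestAmplitudes:
    def test_face_harmonic_set(self):
        assert len(FACE_HARMONICS) == 12
        assert 6.0 not in FACE_HARMONICS and 12.0 not in FACE_HARMONICS
        assert FACE_HARMONICS[0] == 1.2 and FACE_HARMONICS[-1] == 16.8

    def test_base_harmonic_set(self):
        assert BASE_HARMONICS == (6.0, 12.0, 18.0)

    def test_target_equal_to_surround_gives_zero(self):
        spec = make_spectrum(np.full(4000, 2.0), fs=512.0)
        assert baseline_subtracted_amplitude(spec, 6.0) == pytest.approx(0)

    def test_target_minus_surround(self):
        amps = np.full(4000, 2.0)
        spec = make_spectrum(amps, fs=512.0)
        k = spec.bin_index(6.0)
        amps[k] = 5.0
        assert baseline_subtracted_amplitude(spec, 6.0) == pytest.approx(3)

    def test_baseline_subtraction_matches_brute_force(self, rng):
        for _ in range(200):
            amps = rng.gamma(2.0, 1.0, 2000)
            spec = make_spectrum(amps, fs=512.0, n_samples=33707)
            f = rng.uniform(1.0, 20.0)
            k = round(f * 33707 / 512.0)
            lo, hi = max(0, k - 25), min(len(amps), k + 26)
            surround = [amps[i] for i in range(lo, hi)
                        if i not in (k - 1, k, k + 1)]
            expected = amps[k] - np.mean(surround)
            assert baseline_subtracted_amplitude(spec, f) == \
                pytest.approx(expected)

    def test_face_amplitude_sums_twelve_harmonics(self, rng):
        amps = rng.gamma(2.0, 1.0, 20000)
        spec = make_spectrum(amps, fs=512.0, n_samples=33707)
        expected = sum(baseline_subtracted_amplitude(spec, f)
                       for f in FACE_HARMONICS)
        assert face_selective_amplitude(spec) == pytest.approx(expected)

    def test_unit_elevations_sum_to_twelve(self):
        amps = np.full(20000, 1.0)
        spec = make_spectrum(amps, fs=512.0, n_samples=33707)
        for f in FACE_HARMONICS:
            amps[spec.bin_index(f)] += 1.0
        assert face_selective_amplitude(spec) == pytest.approx(12.0,
                                                               rel=1e-3)

    def test_base_amplitude(self):
        amps = np.full(20000, 1.0)
        spec = make_spectrum(amps, fs=512.0, n_samples=33707)
        for f in BASE_HARMONICS:
            amps[spec.bin_index(f)] += 2.0
        assert base_amplitude(spec) == pytest.approx(6.0, rel=1e-3)


class TestSignalNoiseIndices:
    def test_scale_invariance(self, rng):
        amps = rng.gamma(2.0, 1.0, 4000)
        s1 = signal_noise_indices(make_spectrum(amps, fs=512.0,
                                                n_samples=33707))
        s2 = signal_noise_indices(make_spectrum(2 * amps, fs=512.0,
                                                n_samples=33707))
        assert s1 == pytest.approx(s2)

    def test_signal_index_monotone_in_harmonic_amplitude(self):
        base = np.full(4000, 1.0)
        values = []
        for boost in (0.0, 0.5, 1.0, 2.0):
            amps = base.copy()
            spec = make_spectrum(amps, fs=512.0, n_samples=33707)
            for h in (1, 2, 3, 4):
                amps[spec.bin_index(h * 1.2)] += boost
            values.append(signal_noise_indices(spec)[0])
        assert np.all(np.diff(values) > 0)
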