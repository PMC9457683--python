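"""Notch/low-pass filtering, face-locked epoching and onset detection."""

import numpy as np
import pytest

from fpvs.data_model import StimulusProtocol
from fpvs.timing import (EpochAverage, butter_lowpass, contact_onset,
                         face_epoch_average, face_onset_times, fft_notch,
                         group_latency, onset_correlation)

FS = 512.0


def make_epoch(values, fs=FS):
    n_pre = int(round(2 / 6 * fs))
    times = (np.arange(len(values)) - n_pre) / fs
    return EpochAverage(times=times, values=np.asarray(values, float),
                        fs=fs, n_faces=10)


def step_epoch(onset_s, height=1.0, noise_sd=0.0, rng=None, fs=FS):
    n = int(round(7 / 6 * fs))
    n_pre = int(round(2 / 6 * fs))
    t = (np.arange(n) - n_pre) / fs
    v = np.where(t >= onset_s, height, 0.0)
    if noise_sd:
        v = v + rng.normal(0, noise_sd, n)
    ep = make_epoch(v, fs)
    base = (ep.times >= -0.166) & (ep.times <= 0)
    ep.values = ep.values - ep.values[base].mean()
    return ep


class TestFFTNotch:
    def test_removes_6hz(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.cos(2 * np.pi * 6.0 * t)
        y = fft_notch(x, FS)
        assert np.sqrt(np.mean(y ** 2)) < 0.01 * np.sqrt(np.mean(x ** 2))

    def test_passband_untouched(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.cos(2 * np.pi * 1.2 * t)
        y = fft_notch(x, FS)
        assert np.sqrt(np.mean((y - x) ** 2)) < 0.01

    def test_composite_reduces_to_face_component(self):
        t = np.arange(int(30 * FS)) / FS
        face = np.cos(2 * np.pi * 1.2 * t)
        x = face + 0.8 * np.cos(2 * np.pi * 6 * t) \
            + 0.5 * np.cos(2 * np.pi * 12 * t)
        y = fft_notch(x, FS)
        assert np.sqrt(np.mean((y - face) ** 2)) \
            < 0.02 * np.sqrt(np.mean(x ** 2))

    def test_narrow_width_widened_to_one_bin(self):
        t = np.arange(int(5 * FS)) / FS  # bin width 0.2 Hz > 0.07
        x = np.cos(2 * np.pi * 6.0 * t)
        y = fft_notch(x, FS)
        assert np.sqrt(np.mean(y ** 2)) < 0.05


class TestButterLowpass:
    def test_dc_preserved(self):
        y = butter_lowpass(np.full(2000, 3.0), FS)
        assert np.allclose(y, 3.0)

    def test_50hz_attenuation_matches_analytic(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.cos(2 * np.pi * 50.0 * t)
        y = butter_lowpass(x, FS)
        # forward-backward order-4 Butterworth: |H|^2 at 50 Hz.
        # The analog magnitude formula is the reference; the digital
        # (bilinear) design warps slightly at 50 Hz / 512 Hz, so a 20%
        # band covers the design family. An exact digital check follows.
        expected_analog = 1.0 / (1.0 + (50.0 / 30.0) ** 8)
        mid = slice(2000, -2000)
        gain = np.max(np.abs(y[mid])) / np.max(np.abs(x[mid]))
        assert gain == pytest.approx(expected_analog, rel=0.2)
        from scipy import signal as sps
        sos = sps.butter(4, 30.0, btype="low", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[50.0 / (FS / 2) * np.pi])
        assert gain == pytest.approx(abs(h[0]) ** 2, rel=0.01)

    def test_5hz_preserved(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.cos(2 * np.pi * 5.0 * t)
        y = butter_lowpass(x, FS)
        mid = slice(2000, -2000)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.01)


class TestEpochAverage:
    def test_epoch_duration_is_seven_base_cycles(self, protocol):
        trace = np.random.default_rng(0).standard_normal(int(74 * FS))
        ep = face_epoch_average(trace, FS, protocol,
                                onset_sample=int(2 * FS))
        dur = ep.times[-1] - ep.times[0] + 1 / FS
        assert dur == pytest.approx(7 / 6, abs=2 / FS)
        assert dur == pytest.approx(1.17, abs=0.01)

    def test_baseline_mean_is_zero(self, protocol):
        trace = np.random.default_rng(1).standard_normal(int(74 * FS))
        ep = face_epoch_average(trace, FS, protocol,
                                onset_sample=int(2 * FS))
        base = (ep.times >= -0.166) & (ep.times <= 0)
        assert ep.values[base].mean() == pytest.approx(0.0, abs=1e-12)

    def test_impulse_train_recovered_at_zero(self, protocol):
        trace = np.zeros(int(74 * FS))
        onset_sample = int(2 * FS)
        for t0 in face_onset_times(protocol):
            trace[onset_sample + int(round(t0 * FS))] = 1.0
        ep = face_epoch_average(trace, FS, protocol,
                                onset_sample=onset_sample)
        peak_t = ep.times[np.argmax(ep.values)]
        assert abs(peak_t) <= 1 / FS

    def test_too_short_trace_rejected(self, protocol):
        with pytest.raises(ValueError):
            face_epoch_average(np.zeros(512), FS, protocol)


class TestContactOnset:
    def test_step_recovered_exactly(self, rng):
        ep = step_epoch(0.100, height=10.0, noise_sd=1.0, rng=rng)
        onset = contact_onset(ep)
        assert onset == pytest.approx(0.100, abs=1.5 / FS)

    def test_flat_response_gives_none(self):
        assert contact_onset(make_epoch(np.zeros(597))) is None

    def test_brief_excursion_rejected_by_persistence_rule(self):
        n = int(round(7 / 6 * FS))
        n_pre = int(round(2 / 6 * FS))
        v = np.zeros(n)
        t = (np.arange(n) - n_pre) / FS
        v[(t >= 0.1) & (t < 0.12)] = 10.0  # 20 ms blip only
        assert contact_onset(make_epoch(v)) is None

    def test_zero_noise_step_recovered(self):
        ep = step_epoch(0.150, height=1.0)
        assert contact_onset(ep) == pytest.approx(0.150, abs=1.0 / FS)

    def test_shift_equivariance(self, rng):
        base = contact_onset(step_epoch(0.100, 10.0, 1.0,
                                        np.random.default_rng(3)))
        shifted = contact_onset(step_epoch(0.150, 10.0, 1.0,
                                           np.random.default_rng(3)))
        assert shifted - base == pytest.approx(0.050, abs=2 / FS)


class TestGroupLatency:
    def test_identical_stepped_contacts_zero_width_ci(self):
        eps = [step_epoch(0.100, height=1.0) for _ in range(6)]
        out = group_latency(eps, signal_class="HF", B_outer=50,
                            B_inner=100, seed=0)
        assert out.onset == pytest.approx(0.100, abs=2 / FS)
        assert out.onset_ci[1] - out.onset_ci[0] == pytest.approx(0.0)

    def test_offset_of_transient_response(self):
        n = int(round(7 / 6 * FS))
        n_pre = int(round(2 / 6 * FS))
        t = (np.arange(n) - n_pre) / FS
        v = np.where((t >= 0.1) & (t < 0.4), 1.0, 0.0)
        eps = [make_epoch(v) for _ in range(6)]
        out = group_latency(eps, signal_class="HF", B_outer=30,
                            B_inner=100, seed=1)
        assert out.onset == pytest.approx(0.1, abs=2 / FS)
        assert out.offset == pytest.approx(0.4, abs=3 / FS)

    def test_no_response_flagged(self):
        eps = [make_epoch(np.zeros(597)) for _ in range(6)]
        out = group_latency(eps, signal_class="HF", B_outer=20,
                            B_inner=50, seed=2)
        assert out.onset is None
        assert "no-timepoint-reaches-criterion" in out.flags

    def test_lf_hilbert_rectifies_polarity(self, rng):
        """Contacts with opposite polarity must not cancel for LF."""
        n = int(round(7 / 6 * FS))
        n_pre = int(round(2 / 6 * FS))
        t = (np.arange(n) - n_pre) / FS
        resp = np.where((t >= 0.1) & (t < 0.4),
                        np.sin(2 * np.pi * 8 * (t - 0.1)), 0.0)
        eps = []
        for i in range(8):
            sign = 1 if i % 2 == 0 else -1
            eps.append(make_epoch(sign * resp
                                  + rng.normal(0, 0.05, n)))
        out = group_latency(eps, signal_class="LF", B_outer=40,
                            B_inner=100, seed=3)
        # Hilbert rectification smears energy slightly before the true
        # onset, so the detected onset may lead 0.1 s; the point is
        # that opposite polarities do not cancel the group response
        assert out.onset is not None
        assert 0.0 <= out.onset <= 0.15


class TestOnsetCorrelation:
    def test_identical_vectors(self, rng):
        x = rng.random(20)
        assert onset_correlation(x, x, B=50)["r"] == pytest.approx(1.0)

    def test_known_correlation_recovered(self, rng):
        n, rho = 60, 0.5
        z = rng.standard_normal(n)
        x = 0.1 + 0.02 * z
        y = 0.1 + 0.02 * (rho * z
                          + np.sqrt(1 - rho ** 2) * rng.standard_normal(n))
        out = onset_correlation(x, y, B=100)
        assert out["r"] == pytest.approx(rho, abs=0.15)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            onset_correlation([0.1] * 10, list(np.random.rand(10)))
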