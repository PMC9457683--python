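"""End-to-end per-contact quantification over a cohort of recordings.

Ties the stages together: usable-window extraction, integer-cycle
cropping, time-domain averaging across sequences, FFT, harmonic-summed Z,
baseline-subtracted amplitudes and four-way classification — once on the
raw trace (LF) and once on the broadband envelope (HF).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import SequenceRecording, StimulusProtocol
from .envelope import (HFConfig, envelope_usable_segment, hf_envelope_batch)
from .spectral import (AmplitudeSpectrum, classify_contact,
                       crop_integer_cycles, face_selective_amplitude,
                       base_amplitude, lf_spectrum, quantify_spectrum)


def usable_trace(rec: SequenceRecording, channel: int = 0) -> np.ndarray:
    """Samples from analysis_start (end of fade-in) onward."""
    i0 = rec.onset_sample + int(round(rec.protocol.analysis_start * rec.fs))
    return rec.data[channel, i0:]


def lf_contact_spectrum(sequences: list[SequenceRecording],
                        channel: int = 0) -> AmplitudeSpectrum:
    """LF amplitude spectrum of one contact (average across sequences)."""
    proto = sequences[0].protocol
    fs = sequences[0].fs
    cropped = [crop_integer_cycles(usable_trace(r, channel), fs, proto)[0]
               for r in sequences]
    return lf_spectrum(cropped, fs, source_class="LF")


def hf_contact_spectrum(sequences: list[SequenceRecording],
                        config: HFConfig = HFConfig(),
                        channel: int = 0) -> AmplitudeSpectrum:
    """HF envelope spectrum of one contact (average across sequences)."""
    proto = sequences[0].protocol
    fs = sequences[0].fs
    traces = np.vstack([r.data[channel] for r in sequences])
    env = hf_envelope_batch(traces, fs, config,
                            onset_sample=sequences[0].onset_sample)
    usable = envelope_usable_segment(env, proto)
    cropped, _ = crop_integer_cycles(usable, env.fs_env, proto)
    return lf_spectrum(list(cropped), env.fs_env, source_class="HF")


def per_sequence_face_amplitudes(sequences: list[SequenceRecording],
                                 signal: str = "LF",
                                 config: HFConfig = HFConfig(),
                                 channel: int = 0) -> np.ndarray:
    """Face-selective amplitude of each individual sequence.

    The across-sequence SD of these values is the noise estimate feeding
    the maximum-expected-correlation analysis.
    """
    proto = sequences[0].protocol
    fs = sequences[0].fs
    amps = []
    for rec in sequences:
        if signal == "LF":
            spec = lf_contact_spectrum([rec], channel)
        else:
            spec = hf_contact_spectrum([rec], config, channel)
        amps.append(face_selective_amplitude(spec))
    return np.asarray(amps)


def quantify_cohort(recordings: dict, contact_table: pd.DataFrame,
                    hf_config: HFConfig = HFConfig(),
                    with_hf: bool = True,
                    with_indices: bool = False) -> pd.DataFrame:
    """Quantify every contact of a cohort; returns one row per contact.

    Columns: z_lf, face_amp_lf, base_amp_lf (+ _hf variants when
    ``with_hf``) and the four-way classification.
    """
    rows = []
    for _, c in contact_table.iterrows():
        seqs = recordings[c["contact_id"]]
        row = dict(c)
        spec_lf = lf_contact_spectrum(seqs)
        q_lf = quantify_spectrum(spec_lf, with_indices=with_indices)
        row.update(z_lf=q_lf.z_face, face_amp_lf=q_lf.face_amp,
                   base_amp_lf=q_lf.base_amp)
        if with_indices:
            row.update(signal_index_lf=q_lf.signal_index,
                       noise_index_lf=q_lf.noise_index)
        if with_hf:
            spec_hf = hf_contact_spectrum(seqs, hf_config)
            q_hf = quantify_spectrum(spec_hf, with_indices=with_indices)
            row.update(z_hf=q_hf.z_face, face_amp_hf=q_hf.face_amp,
                       base_amp_hf=q_hf.base_amp)
            if with_indices:
                row.update(signal_index_hf=q_hf.signal_index,
                           noise_index_hf=q_hf.noise_index)
            row["classification"] = classify_contact(q_lf.z_face,
                                                     q_hf.z_face)
        rows.append(row)
    return pd.DataFrame(rows)
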