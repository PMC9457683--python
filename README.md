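# fpvs-seeg

Dual-signal frequency-tagging analysis for intracranial (SEEG)
recordings of the human ventral occipito-temporal cortex, with a
synthetic cohort generator providing known ground truth.

## The problem

During fast periodic visual stimulation, images appear at 6 Hz with a
face as every fifth stimulus, so face-selective neural activity is
tagged at exactly 1.2 Hz and its harmonics. Two kinds of intracranial
signal carry that tag: the phase-locked low-frequency evoked response
(**LF**, read from the FFT of the averaged raw trace) and the
non-phase-locked high-frequency broadband response (**HF**, read from
the FFT of the 40–160 Hz Morlet amplitude envelope). This package
implements the full analysis chain needed to quantify and compare the
two signals across hundreds of depth-electrode contacts:

* bipolar montage construction and anatomical labelling rules
  (`fpvs.data_model`);
* integer-cycle cropping, time-domain averaging, amplitude spectra and
  the harmonic-summed Z statistic — Z = (centre − mean of 48 surround
  bins)/SD over the elementwise sum of four 51-bin segments centred on
  1.2, 2.4, 3.6 and 4.8 Hz; Z > 3.1 marks a face-selective contact —
  plus baseline-subtracted face (Σ over 12 harmonics, 1.2–16.8 Hz
  excluding 6 and 12 Hz) and base (6 + 12 + 18 Hz) amplitudes
  (`fpvs.spectral`);
* the broadband envelope transform: Morlet wavelets 40–160 Hz in 3 Hz
  steps with 5→11 adaptive cycles, percent-change normalisation
  against a pre-stimulus baseline, decimation to 85.3 Hz
  (`fpvs.envelope`);
* cohort maps: overlapping 12×12×100 mm Talairach voxels stepped by
  3 mm, postero-anterior profiles, winsorized means, threshold
  matching, percentile bootstrap / permutation inference and
  Benjamini–Hochberg FDR (`fpvs.maps`);
* spatial extent along arrays: profile folding around the peak contact
  and exponential-decay fits y(x) = p·(1−d)^x + o, with the extent at
  fraction f given by ln(f)/ln(1−d) (`fpvs.extent`);
* LF↔HF correspondence: log-Pearson correlation, the Monte-Carlo
  noise ceiling (maximum expected correlation) and the face-selectivity
  index FSI = face/(face+base) (`fpvs.correspondence`);
* response timing: FFT notch of the base-rate response, zero-phase
  30 Hz low-pass, 1.17 s face-locked epochs (41 ms contrast shift),
  2.58-SD / 30 ms onset detection and nested-bootstrap group latencies
  (`fpvs.timing`);
* a ground-truth synthetic cohort generator (`fpvs.synth`) and
  vectorised null-calibration harnesses (`fpvs.calibration`).

The numbered scripts under `analysis/` walk the full pipeline over a
simulated cohort and write their tables to `results/`.

## Worked example

```python
import numpy as np
from fpvs.synth import SimulationConfig, simulate_contact
from fpvs.cohort import lf_contact_spectrum, hf_contact_spectrum
from fpvs.spectral import quantify_spectrum, classify_contact

cfg = SimulationConfig(seed=3)          # 70 s sequences, 512 Hz
recs, truth = simulate_contact(cfg)     # 4 sequences, one contact

q_lf = quantify_spectrum(lf_contact_spectrum(recs))
q_hf = quantify_spectrum(hf_contact_spectrum(recs))
print(f"LF: Z = {q_lf.z_face:.1f}, face amplitude "
      f"{q_lf.face_amp:.2f} uV (injected {truth.lf_face_amp:.2f})")
print(f"HF: Z = {q_hf.z_face:.1f}")
print("class:", classify_contact(q_lf.z_face, q_hf.z_face))
```

prints

```
LF: Z = 38.4, face amplitude 4.84 uV (injected 4.68)
HF: Z = 14.6
class: LF+HF+
```

a strongly face-selective simulated contact: both Z statistics clear
the 3.1 threshold, and the summed face-harmonic amplitude recovers the
injected 4.68 µV within the estimator's noise (the small positive
excursion is the Rician noise floor at this SNR). Running
`python analysis/02_quantify_contacts.py` applies the same
quantification to a 128-contact cohort and reproduces the
characteristic asymmetry of the two signals — many LF-only contacts, a
core of LF+HF+ contacts, almost no HF-only contacts.

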