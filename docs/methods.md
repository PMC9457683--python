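# Methods

## The measurement problem

Fast periodic visual stimulation (FPVS) presents images at a fixed base
rate of 6 Hz with a face appearing as every fifth stimulus, so any
face-selective neural response is tagged at exactly 6/5 = 1.2 Hz and its
harmonics. In intracranial (SEEG) recordings two signals carry this tag:

* **LF** — the stimulus-phase-locked low-frequency evoked response, read
  directly from the FFT of the time-averaged raw trace;
* **HF** — the non-phase-locked 40–160 Hz broadband ("high-gamma")
  response, read from the FFT of the broadband amplitude envelope, whose
  gain is modulated once per face.

The package quantifies both signals with identical frequency-domain
machinery and compares their significance statistics, spatial maps,
amplitude decay along depth-electrode arrays, functional correspondence
and response latencies. Because the underlying patient recordings are
not distributed with the package, all analyses run against a synthetic
cohort generator whose injected quantities are known exactly.

## Signal pipeline

**Montage and labels.** Recordings are re-referenced to a bipolar
montage (each contact minus its directly adjacent, more medial
neighbour; one channel fewer per array; pairs spanning a missing contact
are skipped and logged). A bipolar site in gray matter (including
amygdala/hippocampus) keeps its own anatomical label; a white-matter
site takes the label of a gray-matter reference; white/white pairs are
excluded. The 14 ventral occipito-temporal region labels group into
OCC / PTL / ATL / MTL main regions.

**Cropping and averaging.** Each 70 s sequence is analysed from 2 s
(end of fade-in) to 68 s, cropped to the largest integer number of face
cycles — 79 cycles ≈ 65.8 s — so the face frequency falls exactly on
FFT bin 79 (up to one-sample rounding; N = round(K·fs/1.2)). Sequences
are averaged in the time domain before the FFT: phase-locked components
survive, non-phase-locked noise shrinks as 1/√S.

**Amplitude spectra** use the single-sided 2/N convention (a unit
cosine on an exact bin has amplitude 1). The convention is a
documentation choice only: the Z statistic and all indices are
scale-invariant.

**Harmonic-summed Z.** The spectrum is cut into four 51-bin segments
centred on 1.2, 2.4, 3.6 and 4.8 Hz; segments are summed elementwise
and the centre bin is standardised against the 48 surrounding bins
(25 per side minus the two adjacent). The population (n-denominator)
SD is the default (`ddof` configurable). Z > 3.1 marks significance,
nominally one-tailed p < 0.001.

*Calibration caveat (measured, not assumed).* The nominal p assumes Z
is standard normal. With the SD estimated from only 48 bins the
statistic is t-like (scale inflation ≈ 1.045) and the Rayleigh-sum
segment is right-skewed (≈ 0.34), so the true null exceedance of 3.1 is
about 0.004–0.005 for a locally flat spectrum — measured both by direct
simulation of the idealised white-noise case and by pushing 20,000
noise-only contacts through the full HF pipeline. The LF pipeline lands
near 0.003 because the 1/f slope inflates the surround SD. Users should
read "Z > 3.1" as "p ≈ 0.003–0.005 one-tailed", not 0.001.

**Amplitude quantification.** Baseline-subtracted amplitude = bin
amplitude minus the mean of up to 25 bins per side (excluding the two
adjacent; truncated at spectrum edges, never below 10 bins per side).
The face-selective amplitude sums the 12 face harmonics from 1.2 to
16.8 Hz excluding 6 and 12 Hz; the base amplitude sums 6, 12 and 18 Hz.

*Estimator bias (measured, derived).* At a bin carrying signal s over
complex-Gaussian noise of component SD σ, the expected estimate is
≈ s + σ²/s − 1.2533σ (Rician mean minus the Rayleigh surround mean):
relative bias ≈ −1.25/x + 1/x² at per-bin SNR x = s/σ. Recovery is
therefore exact only asymptotically: |bias| < 5% needs x ≥ 25 per
harmonic, far above the x ≈ 3–5 implied by a harmonic-summed Z near 10,
where the summed face amplitude is underestimated by roughly a third.
The same floor-suppression steepens apparent spatial decay when distant
contacts' amplitudes approach the noise floor. Both effects are
properties of the estimator itself, inherited by design.

**Signal/noise indices.** The Z decomposition used here normalises each
scored harmonic bin by its local surround mean (removing the 1/f trend):
signal index = Σ (normalised centre − 1) over harmonics 1–4; noise
index = mean surround coefficient of variation. These definitions are
explicit, scale-invariant stand-ins — their absolute values are not
comparable to any external convention.

**HF envelope.** Complex Morlet wavelets from 40 to 160 Hz in 3 Hz
steps, cycles increasing linearly 5 → 11 (timing variant 3.2 → 9),
σ_t = n_cycles/(2πf). Implementation: frequency-domain Gaussian
filtering of the reflection-padded trace, with decimation by 6
(512 → 85.3 Hz) computed exactly via the spectral aliasing identity
(picking every 6th sample folds the spectrum modulo N/6) — verified
against direct time-domain convolution to < 1e-6 relative error. Each
frequency's envelope is converted to percent signal change against the
pre-stimulus −1.6 to −0.3 s window before averaging across frequencies,
equalising contributions across the 1/f amplitude gradient; the
normalisation assumes every wavelet band has nonzero baseline power
(true of physiological signals; degenerate for a single pure tone). The
envelope then enters the same crop/average/FFT machinery as the raw
trace. A stationary 18 Hz phase-locked component contributes < 1% of
its amplitude to the envelope at 1.2 Hz (leakage guard, tested).

## Group-level statistics

Voxel maps use overlapping 12 × 12 × 100 mm windows stepped 3 × 3 ×
100 mm (half-open bins anchored at the Talairach origin); an interior
contact falls in 16 (x, y) voxels. Per-voxel inference on proportions
is a percentile bootstrap (B = 2000; p = fraction of resamples with
zero significant contacts). Postero-anterior profiles use 12 mm / 3 mm
windows along y, hemispheres collapsed, optionally z-scored across bins.
Winsorized means clip round(0.1·n) values per tail (none for n < 5).
Threshold matching returns the (N+1)-th largest Z; ties produce the
nearest achievable count with a warning. Permutation tests shuffle
labels (sign-flip for paired designs) with the +1 small-sample
correction; multiplicity is Benjamini-Hochberg FDR (statsmodels
backend, brute-force step-up oracle in the tests).

## Spatial extent

Arrays are included when LF and HF peak contacts lie within 3.5 mm
(peak ties break toward the medial end). Profiles are folded around the
peak (equidistant arms averaged; lone arms kept), averaged across
arrays, and fitted with y(x) = p·(1−d)^x + o by bounded least squares
(p ≥ 0, d ∈ [0, 0.999], o free; five deterministic starts over d). The
extent at fraction f is ln(f)/ln(1−d) — independent of p and o since
the curve's amplitude range is p; d = 0 yields a flagged infinite
extent. Cluster size is the contiguous significant run containing the
peak, with length n × 3.5 mm (the count convention: 3.83 contacts ↔
13.4 mm); the (n−1) × 3.5 gap convention is exposed alongside.
LF-vs-HF extent differences are tested by swapping the signal labels
within arrays, refitting, and recomputing the extent difference.

## Correspondence and noise ceiling

Amplitude correlations are Pearson on log-transformed pairs (amplitudes
are right-skewed); non-positive baseline-subtracted amplitudes cannot
be logged and are excluded with a count. The maximum expected
correlation (MEC) estimates each signal's reproducibility as the mean
over 2000 Monte-Carlo iterations of corr(log measured, log (measured +
SD·z)), with the across-sequence amplitude SD as the noise scale and
noise added on the linear scale; MEC = min of the two reproducibilities,
and observed r / MEC says how much of the attainable correlation is
reached.

*Calibration of the shortcut.* Correlating the measured values against
a re-noised copy of themselves is not literal test-retest: writing S
and N for the log-scale signal and measurement-noise variances, the
shortcut gives √((S+N)/(S+N+σ²)) while the true attenuation of two
independently noisy measurements is S/(S+N). With σ equal to the
across-sequence SD and measurements averaging n sequences (so N =
σ²/n), the two agree to first order in N/S exactly when n = 2. The
ceiling-recovery analyses therefore use two-sequence cohorts, where the
observed/MEC ratio is ≈ 1 by construction; at larger n or heavy noise
the MEC is conservative (underestimates the ceiling).

The face-selectivity index is FSI = face/(face + base) with amplitudes
averaged across the contact set *before* the ratio, which keeps the
index in [0, 1]; negative means clip with a flag.

## Timing

The base-rate response is removed with an FFT notch (±0.035 Hz, widened
to one bin if narrower) at 6, 12, 18 and 24 Hz; the LF signal is
additionally low-passed at 30 Hz (zero-phase order-4 Butterworth —
forward-backward, chosen because latency is the endpoint and phase
delay would bias it). Epochs of [−2, +5] base cycles (1.1667 s,
reported as 1.17 s) are cut around each face onset shifted forward by
41 ms (the ~50%-contrast point of the sinusoidal stimulation; the exact
quarter-cycle 41.67 ms is available by argument), averaged, and
baseline-corrected on [−0.166, 0] s. A contact's onset is the first
time in 0–700 ms that the response leaves the baseline mean ± 2.58 SD
band for ≥ 30 ms; with a strictly noise-free baseline the band
degenerates to exact departure from the baseline mean, so a step onset
is recovered exactly. Group latencies use the nested bootstrap: inner
resampling of contacts gives a per-timepoint p (fraction of bootstrap
means not exceeding their own baseline mean; onset = first p < 0.01
sustained 30 ms, offset = end of that run), and the outer loop repeats
this to yield latency distributions and percentile CIs. LF responses
are Hilbert-rectified before group averaging so polarity differences do
not cancel; rectification smears some energy just before the true
onset, a known mild early bias.

## Synthetic cohorts

`simulate_sequence` builds: 1/f^(β/2) amplitude-shaped Gaussian noise
(β = 1.5, RMS 10 µV); phase-locked cosines at the face harmonics
(defaults sum to 4.68 µV with a geometric roll-off; the 5th and 10th
face harmonics are zero because those bins belong to the base response)
and base harmonics (2.0/0.8/0.3 µV); and a 40–160 Hz Gaussian carrier
(RMS 5 µV) whose gain rises by `hf_gain_depth` in a raised-cosine burst
(0.3 s) after each face, `response_onset_s` (90 ms) after face onset.
The default depth 0.1 reproduces the strong LF ≫ HF asymmetry seen in
VOTC cohorts (mean Z ≈ 3.6 vs 1.3). Responses (not noise) follow the
2 s fade-in/out ramps. Across-sequence variability is a multiplicative
lognormal factor with unit mean and SD `sequence_jitter_sd` (0.2).
Arrays decay injected amplitude as (1−d)^x from a peak contact
(d = 0.2/mm default, 3.5 mm spacing); cohorts draw Talairach positions
over x ±25–45, y −75…−5, z −20…−5 mm and scale amplitudes by a linear
posterior→anterior multiplier (−0.012/mm from y = −70, floor 0.05).
Sequences carry 2 s of pre-stimulus data for the envelope baseline.
Two summary-level samplers (`simulate_z_cohort`,
`simulate_amplitude_cohort`) generate statistic-level cohorts (Z values
or amplitudes directly) for map- and ceiling-level analyses where the
trace pipeline is not the object under test; both are labelled
synthetic stand-ins in their docstrings.

What the generator does **not** emulate: epileptic discharges, line
noise, electrode impedance drift, non-stationary background spectra,
volume conduction across arrays, or correlated noise between contacts.
Passing tests therefore demonstrate correctness of the analysis
machinery and recoverability of injected structure, not robustness to
every artifact of clinical recordings.

## Problem sizes and numerical choices

Test and analysis problem sizes are chosen so the full suite runs on a
single CPU in minutes: null calibration uses 20,000 noise-only contacts
(LF at the full 70 s / 2 sequences; HF at 48 s — 52 face cycles, the
shortest duration keeping the four harmonic segments disjoint — with
one sequence; the null level is insensitive to duration and averaging);
extent recovery uses 30 arrays × 11 contacts per decay rate at a noise
level giving amplitude-estimate SDs ≈ 1% of peak; timing coverage uses
50 cohorts of 12 contacts with a 200 × 100 nested bootstrap (the full
1000 × 1000 remains available); the analysis drivers use an
8-participant, 128-contact cohort with 48 s sequences. FFT lengths for
the wavelet transform are padded to 5-smooth lengths divisible by the
decimation factor; reflection padding spans 6σ_t of the longest
wavelet. Exponential fits report R² from the residual sum of squares;
degenerate (constant) profiles short-circuit to a flagged d = 0.

## Known limitations

* The Z > 3.1 criterion's true false-positive level is ≈ 0.003–0.005,
  not 0.001 (see calibration caveat above).
* Face-selective amplitudes are biased low near the noise floor
  (Rician floor subtraction); group comparisons of amplitudes across
  conditions with very different SNR inherit this bias.
* The MEC shortcut is exactly calibrated only for two-sequence
  averaging; otherwise it is conservative.
* The notch filter removes the face response's own energy at 6, 12, 18
  and 24 Hz, slightly distorting time-domain response shapes — a
  deliberate trade inherited from the design it implements.
* EDF ingestion is a thin optional wrapper; channel selection and
  sequence segmentation from clinical exports are the caller's
  responsibility.
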