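# Methods

## Problem and signal model

Atrial fibrillation (AFIB) is detected here purely from rhythm: the
sequence of inter-beat intervals (IBIs) extracted from a single-channel ECG
or PPG trace. Sinus rhythm produces slowly varying intervals (respiratory
modulation plus small jitter); fibrillation produces large, serially
uncorrelated beat-to-beat changes. Both detectors in this package reduce
the waveform to beats and operate on the interval sequence; waveform
morphology (P-wave absence, fibrillatory waves) is deliberately not used.

## Processing chain

1. **Conditioning.** Savitzky–Golay smoothing (order 4, window 19 samples),
   then a 2nd-order Butterworth band-pass at 0.5–20 Hz, then min–max
   scaling to [0, 10]. The band-pass is applied forward–backward
   (zero-phase): peak *positions* feed every downstream statistic, so phase
   distortion would corrupt the intervals; the effective magnitude response
   is 4th-order. At low sampling rates (50 Hz PPG) the upper band edge is
   clamped to 0.4·fs. The 19-sample smoothing window is kept as a fixed
   sample count regardless of fs (overridable in config); at 50 Hz it spans
   0.38 s and acts as a strong noise filter, which is one reason SNR is
   estimated on the raw signal (below).
2. **Beat detection.** Local maxima above an adaptive threshold: 0.5 × a
   blockwise 99.5th-percentile amplitude envelope (2 s blocks, linearly
   interpolated), floored at 0.25 × the global 99.5th percentile so filter
   ringing in silent stretches cannot fire, with a refractory minimum
   distance of 0.27 s. A high percentile is required because ECG R-spikes
   occupy well under 10% of samples — a median-like envelope would sit on
   baseline ripple. Double detections closer than 250 ms are resolved by
   keeping the larger peak, iterated to a fixed point.
3. **IBI series.** Per-gap intervals in ms; a validity mask marks intervals
   outside **270–1500 ms** (≈ 40–220 bpm; these bounds are standard
   artifact limits, exposed in config); and a sample-and-hold expansion
   assigns every waveform sample the interval of the gap containing it, so
   auxiliary per-sample views have exactly the record's length. Invalid
   intervals are pruned to zero in the masked views and, more importantly,
   exclude every analysis window they touch: a **reliable frame** is a
   sliding window none of whose intersecting intervals is invalid.

## DSP spike-ratio detector

Frames of 8 s slide at a 2 s stride. Within a frame, the first derivative
of the per-gap interval sequence (successive differences, ms) is
thresholded at **50 ms**; the abnormal-change ratio is spike count divided
by the number of beats in the frame. The derivative is taken on the per-gap
sequence, not the sample-expanded trace, whose step edges would repeat each
spike once per sample and make a ms threshold meaningless. Frames with
fewer than 3 beats are skipped rather than counted as zero, to avoid
diluting the mean with uninformative frames. A segment is AFIB when the
mean ratio over all reliable frames exceeds the decision threshold.

The decision threshold is a free parameter (default 0.15). It matters:
healthy subjects with strong respiratory modulation plus jitter near the
upper physiological range reach mean ratios of 0.2–0.4, because a 50 ms
spike threshold sits inside the tail of normal sinus variability. The
package therefore ships a calibration utility that sweeps the threshold on
labelled data and returns the Youden-optimal point (ties toward the lower,
sensitivity-favouring cut). The evaluation protocol in
`afibkit.experiments` calibrates on a disjoint cohort and classifies fresh
data with the result; on the default synthetic populations the two classes
separate completely (NSR ≲ 0.37, AFIB ≳ 0.48), so the calibrated cut is
stable across cohorts.

## HRV-feature classifier

Frames of 15 s slide at a 2 s stride; each reliable frame with ≥ 5
intervals yields one row of seven features of the NN intervals (the
validity-masked IBIs), computed exactly as:

- RMSSD = √(mean of squared successive differences)
- IQRNN = Q3 − Q1 (linear-interpolation quartiles — conventions differ, so
  the convention is fixed and documented)
- CVNN = SD/mean (sample SD, ddof = 1)
- CVSD = RMSSD/mean
- HRMAD = mean absolute deviation of NN in ms by default; a variant on the
  instantaneous heart rate 60000/NN (bpm) is selectable in config. The ms
  default makes MCVNN = HRMAD/median(NN) dimensionless, which is the
  standard form of that index.
- HTI = count(NN) / modal bin height of the NN histogram with a fixed
  1/128 s (7.8125 ms) bin width aligned at zero — the conventional HRV
  triangular-index binning.

Classifiers: random forest (300 trees, √p features), RBF SVM (C = 1,
γ = scale, features standardized, probabilities via a calibrated wrapper)
and KNN (k = 15, standardized). Hyper-parameters are ecosystem defaults
recorded explicitly in config; whether the original features were
standardized is unknowable from the source, so standardization is applied
for the scale-sensitive models only. Splits are subject-wise
(60% of subjects train) and seeded; a leakage checker asserts no subject
appears on both sides. Frame predictions are aggregated per sample by
majority vote with ties going to AFIB (screening favours sensitivity;
configurable).

## Signal-quality gate

Two checks, both thresholds in config: the fraction of valid intervals
must be ≥ 0.75, and the mean beat-level SNR must exceed 5 dB. The SNR
estimator ensemble-averages detected beats (windows of 0.8 × the median
gap, centred on each peak, per-window mean removed) into a template;
"signal" is template power, per-beat "noise" is the residual against the
template, and the report is the mean over beats of the dB ratio, capped at
80 dB for noiseless input. This definition tracks additively constructed
broadband SNR to within ~1.5 dB on synthetic pulses and collapses when
beat detection itself fails — the situation the gate exists to catch. A
spectral definition (fundamental ± harmonic band power vs residual) was
rejected because harmonic leakage caps it near 10–15 dB, making a
constructed 30 dB signal unmeasurable. SNR is measured on the *raw* signal
(with beats located on the conditioned one): measuring after the smoothing
and band-pass stages inflates the figure by ~3–4 dB at 50 Hz.

## Synthetic generator

The generator defines the study conditions for all tests; its defaults are
fixed and not tuned per experiment.

- **NSR:** RRₖ = mean + d·sin(2π·f·tₖ) + N(0, σ²), with respiratory-sinus-
  arrhythmia depth d and frequency f, clipped to [270, 1500] ms.
- **AFIB:** i.i.d. right-shifted Gamma, shift 250 ms (AV-conduction floor),
  shape/scale matched to the target mean and SD — the simplest model with
  the operative fibrillation signature (large uncorrelated successive
  differences). A Markov AV-node model would add realism (clustered short
  intervals) but none of the statistics under test depend on it; this is a
  known limitation.
- **Ectopy:** at a per-minute rate, (RRᵢ, RRᵢ₊₁) → (0.6·RRᵢ, 1.4·RRᵢ₊₁), a
  premature beat with compensatory pause.
- **Waveforms:** ECG beats are Gaussian R-spikes (σ = 12 ms); PPG beats are
  asymmetric gamma-shaped pulses (rise ≈ 0.18 s). White noise is added at a
  target SNR relative to the clean waveform's variance. Ground-truth beat
  positions are returned for round-trip tests. All randomness flows from
  one seed through per-stage substreams.
- **Cohorts:** per-subject parameters are drawn uniformly from physiological
  ranges chosen once: NSR mean RR 700–1000 ms, jitter 15–30 ms, RSA depth
  10–25 ms at 0.2–0.3 Hz, ectopy 0–1/min; AFIB mean RR 550–850 ms, SD
  100–200 ms, no ectopy. Default records are 60 s at 250 Hz (ECG) with
  25 dB additive noise; prevalence 0.5.

What passing on these cohorts does *not* show: robustness to motion
artifact, baseline wander, electrode pop, atrial flutter (regularly
conducted), or PPG amplitude modulation — none of which the generator
emulates. Results on synthetic cohorts are a correctness check of the
pipeline, not a clinical performance claim.

## Numerical and problem-size choices

- Degenerate inputs fail loudly: constant signals ("zero dynamic range"),
  < 2 beats, < 5 intervals per feature frame, single-class training sets
  and single-subject splits are all errors; the quality gate instead always
  returns a report with reasons.
- A record yielding no reliable frame is *unclassifiable*, a third outcome
  distinct from NSR/AFIB.
- Spike comparison is strict (> 50 ms), so a change of exactly 50 ms is
  not abnormal; interval-bound comparison is inclusive.
- Downsampling uses polyphase resampling with a Kaiser (β = 14) window,
  keeping passband error below 10⁻⁶ for in-band tones.
- The evaluation protocol and acceptance script use five 40-subject
  cohorts of 60 s records — large enough that frame- and sample-level
  rates stabilize (≈ 1 840 test frames, 200 samples) while the whole
  computation stays desk-scale (seconds).
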