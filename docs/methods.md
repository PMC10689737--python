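# Methods

This note records the models behind `ppgfeat`, the parameter choices that
matter, and what the synthetic data can and cannot establish.

## Synthetic data model

The generator emulates nighttime wristband PPG from two cohorts with a
known, controllable contrast. It is a signal-level emulation, not a
mechanistic cardiovascular model.

**Interbeat intervals.** An IBI series is `T0 + m(t)` with `T0 = 60000 /
mean_hr` ms and a zero-mean modulation `m` summing a low-frequency sinusoid
at 0.095 Hz (baroreflex band), a high-frequency sinusoid at the respiratory
rate (default 0.25 Hz), and white jitter at 0.3 of the HF amplitude. The
sinusoid amplitude ratio is `sqrt(lf_hf_ratio_target)`; the whole modulation
is rescaled so the realised RMSSD equals `rmssd_target` exactly (modulation
is evaluated on the nominal beat grid, keeping the rescaling linear).
Intervals are clipped to the physiological 300–2400 ms range.

**Pulse shape.** Each beat is one period of a two-Gaussian template: a
systolic bell centred at `spd_fraction` (σ = spd_fraction/3) and an optional
diastolic bell at `diastolic_peak_delay` (σ = (1 − delay)/2.5), minus the
chord joining the raw endpoint values and clipped at zero so the template
starts and ends at its minimum. The Gaussian form makes the first and second
derivatives — and hence the a1/b1/a2/b2/e2 landmarks — analytic, which is
what the fiducial tests check against. The diastolic σ is wide enough that
the waveform still has slope at the beat boundary, producing a sharp
V-shaped trough at every beat onset; with narrower tails the trough becomes
a flat plateau and trough detection cannot be sample-accurate.

**Record synthesis.** Templates are stretched to each IBI by continuous
phase evaluation (a constant IBI train at an integer number of samples is
bit-exactly periodic). Baseline wander is a 0.03 Hz sinusoid with amplitude
`4·noise_sd`, i.e. tied to the noise level so that a noiseless record is
exactly the concatenated pulse train. Motion artifacts are bursts of uniform
noise at ±5× the pulse amplitude, with Poisson-drawn onsets (default 4/h,
10 s long); every burst window is logged in the ground truth.

**Hypnograms.** A four-state Markov chain over {Wake, N1/N2, N3, REM} on
30-s epochs, with persistence chosen so the stationary shares order
N1/N2 > N3 > REM and stage runs of ≥ 5 min occur at realistic frequency.
There is no sleep-cycle macrostructure.

**Cohorts.** Cohort A (non-pregnant-like): 60 bpm mean HR (between-subject
sd 4 bpm), RMSSD 45 ms, LF/HF 0.8, systolic upstroke fraction 0.30, ages
21–28. Cohort B (pregnant-like): +12 bpm, −20% upstroke fraction, −40%
RMSSD, LF/HF 1.5, ages 28–33. These shifts reproduce the direction of the
contrasts the pipeline is designed to detect; their size makes the cohorts
nearly separable per segment, so classification metrics saturate near 1.0 —
the tests therefore check directions, recovery and calibration rather than
any particular real-world AUROC. A follow-up-night parameter shift
(+3 bpm, −15% RMSSD, −10% pulse amplitude, upstroke fraction unchanged) is
provided for two-condition analyses; its size is a free design choice.

What the generator does **not** emulate: reflective-sensor optics, posture
and wrist-position amplitude changes, respiratory-rate drift, sleep-stage
dependence of HRV, arousals, or correlated (non-burst) artifact structure.
Passing tests show the pipeline recovers what the generator encodes; they do
not certify performance on real wristband data.

## Preprocessing

The band-pass is a 3rd-order Butterworth (0.007–10 Hz) applied
forward-backward; zero-phase filtering preserves fiducial timing at the cost
of squaring the magnitude response (the −3 dB corners quoted are those of
the single-pass design). The SII of a 15-s window (1-s hop, half-open
0-based windows) is the Silverman rule-of-thumb bandwidth
`0.9·min(sd, IQR/1.34)·n^(−1/5)` of the window's amplitude sample; a
constant window is defined to have SII 0. The artifact threshold
`mean + 0.8·sd` uses the whole recording's SII series (population sd,
strict inequality), and every flagged 15-s window is unioned into the
per-sample mask.

## Pulse segmentation and fiducials

Beat detection follows the two-moving-average scheme: cardiac-band filter
(0.5–8 Hz, 2nd order, zero-phase), clip negatives, square, compare a 111-ms
peak average against a 667-ms beat average plus 0.02 of the mean squared
signal; blocks at least one peak-window wide mark systolic upstrokes, and
troughs between consecutive peaks delimit pulses (the final trough of one
pulse is the initial trough of the next, so pulse widths and IBIs agree).
At 32 Hz the windows round to 3 and 21 samples.

Derivatives are central differences; the first derivative is smoothed with a
3-point moving average before differentiating again, since raw second
differences at 32 Hz are noise-dominated. All extremum searches break ties
at the earliest index. A detected systolic peak at or after e2 (the
acceleration local maximum marking the systolic/diastolic notch) is treated
as a diastolic-peak misdetection and replaced by the maximum between IT and
e2; the equality case counts as misdetection, and the operation is
idempotent.

## Feature conventions

- Standard deviations are population (divide by n) throughout.
- pNN50 counts successive differences **strictly** greater than 50 ms.
- Poincaré SD1 is the rms of successive differences over √2 (uncentred
  second moment), making SD1 ≡ RMSSD/√2 an exact identity; for stationary
  IBI series the mean successive difference is negligible, so this agrees
  with the centred ellipse-width definition. SD2 is the centred population
  sd of `(x_i + x_{i+1})/√2`, and S = π·SD1·SD2.
- Spectra and sample entropy run on the tachogram resampled at 4 Hz (cubic
  interpolation) after quadratic on-time gap filling of missing beat
  timestamps; gaps over 10 s make a segment unusable for these features.
  Welch windows are 5 min with 50% overlap (shrunk to the series length when
  shorter); band powers are trapezoidal integrals in ms².
- Sample entropy uses m = 2, r = 0.2·sd, Chebyshev distance, self-matches
  excluded, and n − m templates at both lengths, so a strictly periodic
  series gives exactly 0.
- DFA α₁ uses non-overlapping boxes of 4–16 beats with per-box linear
  detrending. This finite box range biases the estimate high on
  uncorrelated noise (Monte-Carlo: 0.588 ± 0.022 instead of the asymptotic
  0.5); the tests encode the honest band for this estimator.
- PRSA uses 50-beat wings; anchors are beats longer (deceleration) or
  shorter (acceleration) than their predecessor, applied on the compacted
  valid-interval sequence; anchors without full wings are dropped. DC/AC use
  the quarter formula `(X(0)+X(1)−X(−1)−X(−2))/4`; IDR/IAR and SDR/SAR use
  the ten points k ∈ [−5, 4]; ADR/AAR is the mean of the 50 pre-anchor
  values minus the mean of the 50 from the anchor on.
- Fragmentation works on the sign sequence of interval increments: zeros
  terminate runs and are never inflections; run lengths count increments;
  an interval belongs to a run if it bounds one of its increments;
  alternation stretches qualify for PAS at ≥ 4 intervals. An all-zero
  increment sequence returns PIP 0, PAS 0, PSS 100, IALS 0.
- Morphology areas integrate above the straight IT–FT chord; width levels
  are fractions of the pulse amplitude above the IT level with sub-sample
  linear interpolation, the diastolic boundary being the **last** downward
  crossing before FT; width ratios are diastolic over systolic, as the
  feature symbols read. Angles use the amplitude-normalized pulse so they
  are unit-free. SP/SPD divides the amplitude at SP by the systolic phase
  duration, mixed units included, as the catalogue defines it.
- Missing values propagate as NaN; a segment needs ≥ 10 valid pulses to
  report morphology, and rows with missing candidate features are dropped
  (with their count) before ranking.

## Ranking and evaluation

Logistic models are effectively unpenalized (C = 10⁶) with features
z-scored on training folds only. Each of the 7 repeats reshuffles its
stratified 7-fold split with a distinct derived seed. Greedy forward
selection is truncated at depth 10 — the popularity vote only ever consumes
the top-10, and a full ranking over 66 candidates would cost ~10× more
logistic fits for no additional output; the Borda vote awards
`depth − position` points, with ties broken by mean rank then name. When
several candidates tie exactly (e.g. multiple features reach AUROC 1.0 on
the synthetic cohorts), the earliest candidate in catalogue order wins the
step, so rankings beyond the first feature are not informative in the
saturated regime. PWD is excluded from the morphology and combined pools:
it is the pulse-period mean and thus mean heart rate in disguise.
Participant-level evaluation uses grouped, class-stratified folds so all
segments of one subject share a fold. Folds whose test set is single-class
are skipped in the AUROC mean.

Effect sizes are Cohen's *d* with the pooled (n−1) sd and a 2000-resample
percentile bootstrap for the 95% CI; significance is the two-sided
Mann–Whitney U. The age sub-analysis averages segments per subject before an
OLS of feature on age; the two-condition comparison reuses the group
machinery with conditions as labels.

## Problem sizes

The shipped study configuration uses 20 subjects per cohort and 1-h records
(≈ 450 accepted segments); recovery checks use 10-min noiseless records and
the determinism check two 30-min subjects. These sizes make every quantity
stable to well within the tolerances tested while keeping a full run in the
single-digit minutes on one core. Larger nights (the 8-h default of
`CohortParams`) change none of the logic, only runtime.

## Known limitations

- Trough-based beat timing at 32 Hz quantizes IBIs to 31.25 ms; frequency-
  domain features on real data would carry the corresponding noise floor.
- The SII threshold is relative to each night's own SII distribution, so a
  recording that is mostly artifact will under-flag.
- e2 detection on heavily damped diastolic waves can fail; affected features
  are emitted as missing rather than imputed.
- The saturated cohort contrast means classification metrics exercise the
  plumbing, not discrimination difficulty; effect-size magnitudes on the
  synthetic cohorts are far larger than any real-data counterpart.
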