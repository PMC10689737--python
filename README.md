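# ppgfeat

Feature pipeline for **wrist-worn photoplethysmography (PPG)** recorded
overnight at low sampling rates (32 Hz), built around the question of which
heart-rate-variability (HRV) and pulse-wave-morphology features best separate
two physiological conditions — the motivating case being healthy pregnant vs
non-pregnant women, where pregnancy raises mean heart rate, shortens the
systolic upstroke of the pulse wave and damps short-term HRV.

Because wristband datasets of this kind are generally not shareable, the
package ships a first-class **synthetic two-cohort generator** with known
ground truth (beat times, artifact windows, hypnograms), so every stage of
the pipeline is testable end to end.

## What it computes

For each subject-night the pipeline:

1. **Preprocesses** the raw signal: zero-phase 3rd-order Butterworth band-pass
   (0.007–10 Hz), optional 128→32 Hz resampling, and motion-artifact masking
   via the **Signal Instability Index** — the Gaussian-KDE bandwidth
   (Silverman's rule) of each sliding 15-s amplitude window, thresholded at
   μ + 0.8σ of the whole-night SII series.
2. **Segments pulses** with the Elgendi two-moving-average systolic-block
   detector and locates fiducial points on the waveform (IT, SP, DP, FT), its
   first derivative (a1, b1, EDV) and second derivative (a2, b2, e2), with an
   e2-based correction of systolic peaks misdetected on the diastolic wave.
3. **Extracts 67 features** per accepted non-overlapping 5-min segment
   (optionally restricted to stage-pure sleep windows from the hypnogram):
   - 30 HRV features: time domain (mean HR, SDNN, RMSSD, pNN50, kurtosis,
     skewness), Welch band powers (VLF/LF/HF, normalized LF/HF, LF/HF),
     Poincaré (SD1, SD2, SD1/SD2, S = πSD1SD2), DFA α₁ (4–16 beats), sample
     entropy (m = 2, r = 0.2·sd), phase-rectified signal averaging
     (DC/AC, IDR/IAR, SDR/SAR, ADR/AAR) and heart-rate fragmentation
     (PIP, PAS, PSS, IALS);
   - 37 morphology features per pulse, averaged over the segment: amplitudes
     (PWA, |b2|), phase durations (PWD = SPD + DPD, t_a1, t_a1b1, t_a2b2,
     t_b2e2, t_s), areas (AUC_total, AUC1, AUC2), velocity/acceleration
     statistics (mean V, IDR(V), mean Acc, MSV, SFV, EDV), diastolic/systolic
     width ratios at 10/25/50/60% of amplitude, normalized time ratios,
     b2/a2 and e2/a2, SP/SPD, the pulsatility index, and rising/falling
     slopes with their angles α, γ.
   Segments are discarded when ≥ 20% of samples are artifact-masked or
   ≥ 20% of interbeat intervals are invalid (outside 0.3–2.4 s or > 20%
   jumps).
4. **Ranks and evaluates features**: Mann–Whitney U and Cohen's *d* (bootstrap
   95% CI) per feature; stepwise-forward selection scored by left-out-fold
   AUROC inside 7 repeats of 7-fold cross-validation with a popularity vote
   for the top-10; and incremental logistic-regression AUROC curves as ranked
   features are added one by one, with segment-level or participant-grouped
   folds. Sub-analyses: per-feature OLS on age, and two-condition (e.g.
   night-1 vs night-2) comparisons.

## Worked example

```python
from ppgfeat.synth import cohort_a_params, cohort_b_params, generate_cohort
from ppgfeat.pipeline import features_dataframe
from ppgfeat.stats import group_compare, rank_features, evaluate_incremental

records = []
for make, seed in ((cohort_a_params, 11), (cohort_b_params, 22)):
    records.extend(r for r, _ in generate_cohort(
        make(n_subjects=4, recording_hours=1.0, seed=seed)))

df = features_dataframe(records)          # one row per accepted 5-min segment
print(f"accepted segments: {len(df)}")
for r in group_compare(df, ["mean_hr", "spd", "rmssd"], seed=0):
    print(f"{r.feature:8s} d = {r.cohens_d:+.2f} "
          f"(95% CI {r.ci_low:+.2f} to {r.ci_high:+.2f}), "
          f"Mann-Whitney p = {r.mann_whitney_p:.2e}")
ranking = rank_features(df, feature_set="combined", depth=5, n_repeats=3, seed=0)
curve = evaluate_incremental(df, ranking.top[:3], seed=0)
print(curve[["k", "feature", "auroc_mean", "auroc_sd"]].to_string(index=False))
```

prints

```
accepted segments: 90
mean_hr  d = -3.93 (95% CI -4.60 to -3.51), Mann-Whitney p = 3.17e-16
spd      d = +11.14 (95% CI +10.30 to +12.59), Mann-Whitney p = 3.17e-16
rmssd    d = +4.19 (95% CI +3.67 to +4.96), Mann-Whitney p = 3.17e-16
 k feature  auroc_mean  auroc_sd
 1 mean_hr         1.0       0.0
 2    sdnn         1.0       0.0
 3   rmssd         1.0       0.0
```

Cohen's *d* here is mean(A) − mean(B), so the pregnant-like cohort B shows
higher mean heart rate (negative *d*), and lower systolic phase duration and
RMSSD (positive *d*) — exactly the contrasts the generator injects. Under the
default cohort separation a single feature already classifies the two groups
perfectly, so the AUROC curve saturates at 1.0 from k = 1.

A console script wraps the same stages:

```bash
ppgfeat simulate --out data/ --seed 1
ppgfeat extract --in data/ --stage full --out features.csv
ppgfeat rank --features features.csv --set combined --seed 1 --out ranking.json
ppgfeat classify --features features.csv --ranking ranking.json \
    --stratify participant --out curve.csv
```

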