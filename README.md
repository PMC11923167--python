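# stridefiber

Analysis of fiber-photometry recordings from behaving mice: ΔF/F
normalization with isosbestic referencing, locomotion bout segmentation,
event-aligned timing metrics, and quantification of optogenetic
stimulation-locked responses. A synthetic-session generator with exact
ground truth makes every stage testable without animal data.

The package is aimed at labs recording bulk calcium (GCaMP) or dopamine
(GRAB-rDA) sensor fluorescence through implanted fibers while tracking
treadmill or open-field locomotion, and at anyone who wants a tested,
scriptable reimplementation of this analysis style rather than one-off
lab code.

## The analysis

**ΔF/F, behavior mode.** Both the signal channel (465/560 nm) and the UV
isosbestic reference (405 nm) are pre-normalized to ΔF/F₀ with
F₀(t) = P₁₀(F over a 5-s sliding window), which removes slow bleaching.
The reference ΔF/F₀ is low-pass filtered (2nd-order Butterworth, 3 Hz
corner, zero-phase) and robustly regressed onto the signal with RANSAC;
the transformed reference a·r(t)+b is subtracted to give the final ΔF/F:

    ΔF/F(t) = ΔF/F₀_sig(t) − [a · LP(ΔF/F₀_ref)(t) + b]

Sessions pass QC only when max ΔF/F > 1.5 % *and* Pearson
r(ΔF/F, reference) < 0.6. Z-scores use the whole-session mean and SD.

**ΔF/F, stim mode.** For stimulation recordings with large evoked offsets
the referenced signal F(t) = a·ref_raw(t)+b comes from a RANSAC regression
of the raw channels, and ΔF/F = (signal − F)/F. No percentile baseline.

**Bout segmentation.** Treadmill: movement/rest binarization at
0.25 cm/s; rests ≤ 0.8 s are absorbed; movement periods shorter than
0.5 s or slower than 0.5 cm/s on average are excluded; onset/offset are
the crossings bounding a valid rest period. Open field: ambulation =
velocity > 2 cm/s for > 0.5 s (runs separated by ≤ 0.5 s merge);
immobility = motion index < 2 % for > 0.5 s, same merging.

**Event-aligned metrics.** Around locomotion onset/offset: peak time
(argmax of the trial-mean z-trace in ±1 s), pre-offset slope (OLS over
[−0.5, 0) s, z/s), and rise time — a 20-ms window slides from −0.5 s in
2-ms steps, its per-trial means are tested against each trial's own
baseline (mean over [−1, −0.5) s) with a right-tailed paired t-test, and
the first run of 5 consecutive windows with p < 0.05 marks the rise.

**Stimulation responses.** Per trial, after subtracting the 5-s
pre-onset baseline: initial elevation (mean ΔF/F over 0.5–1 s
post-onset), maximum reduction (minimum over the final 1 s of
stimulation), and post-stimulation change (mean over 4–9 s post-offset,
the rebound phase). For 3-min ON/OFF open-field epochs, per-epoch mean
velocity is normalized to each animal's own pre-stimulation baseline.

## Worked example

```python
import stridefiber as sf

params = sf.AnalysisParams()                       # all published thresholds
cfg = sf.SynthConfig(duration=600.0, rate=250.0, seed=11, bout_rate=3.0,
                     motion_amp=0.05, event_lag=-0.15)
track, true_bouts = sf.simulate_locomotion(cfg, params)
session, truth = sf.simulate_photometry(cfg, track, true_bouts)

bouts = sf.detect_treadmill_bouts(track, params)
norm = sf.normalize_behavior(session, params, random_state=0)
aligned = sf.align_to_events(norm.t, norm.zscore,
                             bouts.df["onset"].to_numpy(), window=(-2.0, 2.0))
print(len(bouts), norm.qc.max_dff, sf.peak_time(aligned, params),
      sf.rise_time(aligned, params))
```

This prints (formatted):

```
bouts detected: 23 (ground truth 23)
QC: max dF/F = 6.59%  r(signal, reference) = -0.004  included = True
aligned matrix: 23 trials x 1001 lags
peak time: -0.044 s
rise time: -0.154 s
```

The detector recovers all 23 generated bouts exactly; the session passes
QC (strong signal, negligible residual correlation with the reference
after the motion artifact is regressed out); and the rise-time detector
recovers the generated 150-ms activity lead to within 4 ms. The peak sits
near −0.04 s because the transient kernel peaks ~110 ms after its onset.

A CLI mirrors the library for shell use:

```
stridefiber --seed 3 simulate --kind behavior --out sess.h5 --truth-dir truth/
stridefiber bouts sess.h5 --assay treadmill --out bouts.csv
stridefiber --seed 3 normalize sess.h5 --mode behavior --out norm.csv
```

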