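# Methods

This note documents the models, parameters, and numerical choices behind
`stridefiber`, and what the synthetic-data generator does and does not
emulate.

## Normalization

### Behavior mode

Both channels are pre-normalized to ΔF/F₀ against a sliding-percentile
baseline: F₀[i] is the 10th percentile of the raw trace in a 5-s window
centered on sample i and truncated at the session edges. Percentiles
interpolate linearly between order statistics (numpy's definition), which
is pinned so that the brute-force oracle tests are exact. A trailing
window is available (`f0_window_align="trailing"`); centered is the
default because it introduces no phase bias in F₀.

The reference ΔF/F₀ is low-pass filtered with a 2nd-order Butterworth
(3 Hz corner) applied forward–backward (`sosfiltfilt`). Zero-phase
filtering doubles the effective order; the alternative — causal filtering
— would phase-shift the reference relative to the signal and corrupt the
regression. Zero-phase filtering leaves small transients within roughly
one filter time constant of the session edges; tests that assert
near-exact cancellation therefore judge the interior of the trace.

The filtered reference is regressed onto the signal with RANSAC
(scikit-learn `RANSACRegressor`): residual threshold = 1 × the median
absolute deviation of a preliminary OLS fit's residuals, at most 100
trials, seeded. Each hypothesis is an OLS fit on a random 25% subset
rather than a minimal 2-point sample: minimal pairs leave percent-level
slope noise, which reappears after subtraction as uncancelled artifact;
subset hypotheses keep the consensus step (which is what rejects
transient-rich stretches) while estimating slopes nearly as tightly as
OLS. If no subset hypothesis gathers inliers — which happens when the
MAD threshold is tighter than the subset-fit error on nearly noiseless
data — minimal pairs are retried, and only then does the fit fall back
to plain OLS with a logged warning. The RANSAC fit is whole-session; a
per-segment fit would re-estimate gain inside behavioral states and bias
event-locked amplitudes.

### Stim mode

For stimulation sessions the referenced signal F = a·ref_raw + b is fit
on the raw demodulated channels (no percentile baseline, no pre-filter)
and ΔF/F = (signal − F)/F. The regression absorbs channel gain/offset
differences, shared bleaching, and motion artifacts; the evoked response
— sparse in time — is excluded from the consensus set by the robust fit.
F ≤ 0 anywhere is an error rather than a silent clip.

### QC and z-scoring

A session is included only if max ΔF/F exceeds 1.5 % *and* the Pearson
correlation between the final ΔF/F and the transformed reference stays
below 0.6. The 1.5 threshold is interpreted in percent units (0.015 as a
fraction); it is configurable because the alternative reading (a ratio of
1.5) cannot be excluded from the rule's wording. Z-scores use the
whole-session mean and population SD; numpy's pairwise summation keeps
them accurate to ~1e-10 on million-sample traces.

## Bout segmentation

Comparisons follow the printed operators strictly ("> 2 cm/s",
"< 2 % pixel change"): for ambulation and immobility a sample exactly at
threshold belongs to neither class and breaks a run. The treadmill rule
set partitions time into movement and rest bins, so there movement is
v > 0.25 cm/s and rest is its complement. Bout boundaries are reported at
the first sample of the new state; at 1 kHz sub-sample interpolation
would change boundaries by under a millisecond and is not attempted.

Rule order (treadmill): short rests are absorbed into the surrounding
movement *before* the movement duration/velocity filters run, because
onset and offset are defined relative to valid (> 0.8 s) rest periods;
the opposite order is available behind `rest_first=False`. A movement
run at a session edge has no bounding rest crossing and is excluded.
Duration comparisons are done in integer sample counts with a 1e-6-sample
tolerance so that detector and oracle cannot disagree through float
rounding.

For ambulation/immobility, "separated by > 0.5 s" is applied as a merge
rule *first* (runs closer than that fuse, gap samples included in the
bout), then "lasting > 0.5 s" filters the merged runs — applied in the
other order the separation clause would do nothing. Epoch summaries clip
bouts at epoch boundaries and count each bout in the epoch containing its
onset, which keeps frequencies additive across epochs.

## Event-aligned metrics

Alignment extracts raw grid samples (no interpolation); events whose
full window does not fit are dropped and counted. Windows on the lag
grid are half-open [a, b); the 20-ms rise window at 1 kHz holds exactly
20 samples. Peak time is the argmax of the trial-mean trace on [−1, +1] s
with ties resolved to the earliest lag. The pre-offset slope is an OLS
fit over [−0.5, 0) s of the trial-mean trace.

Rise time: per trial, baseline = mean over [−1, −0.5) s; a 20-ms window
starting at −0.5 s advances in 2-ms steps; at each step the per-trial
window means are compared with the baselines by a right-tailed paired
t-test; the first run of 5 consecutive steps with p < 0.05 is the rise,
reported as the center of the run's first window. The search continues
past the anchor to +0.5 s: activity in some populations rises only after
movement onset, and stopping at 0 would make such latencies unreportable.
Steps with zero across-trial variance of the differences are treated as
non-significant (a paired t-test is undefined there).

Calibration: consecutive 20-ms windows at 2-ms steps share 90 % of their
samples, so the 5-consecutive-step rule is a weak multiplicity control.
With band-limited trial noise (1 Hz; see below) the measured null
detection rate over 1000 transient-free sessions is ~0.1, and the test
suite bounds it at 0.20. With white per-sample noise the rule false-fires
on most null sessions — a property of the procedure worth knowing before
applying it to unfiltered data. Detected rise times carry a small early
bias (~8 ms): a window whose trailing samples overlap the step already
tests significant, and the *center* of that window precedes the step.

## Synthetic-data generator

The generator produces the statistical structure the analyses assume,
with exact ground truth; it does not model spiking, sensor saturation,
hemodynamics, or video tracking.

* **Locomotion.** Rest is low-pass jitter capped at 0.1 cm/s (below half
  the 0.25 cm/s threshold, so segmentation truth is unambiguous); bouts
  are smoothstep trapezoids with 0.3-s ramps, placed by a renewal process
  (exponential waiting times floored by the occupied interval) at
  2 bouts/min by default, ~3 s and ~3 cm/s per bout — treadmill-paced
  walking. Ground-truth boundaries are the exact threshold crossings of
  the generated trace, so a correct detector recovers them
  sample-for-sample.
* **Photometry.** signal = (baseline_F + bleach_amp·e^(−t/τ)) +
  transients + gain_s·artifact + white noise; the reference carries its
  own bleaching curve (slightly different amplitude and τ, as two LEDs
  bleach differently), the same artifact with gain 0.8, noise — and no
  transient component. This isosbestic contract means any "signal"
  recovered from the reference is by construction an artifact of the
  pipeline. Transients are double-exponential kernels (rise 50 ms, decay
  500 ms, amplitude 0.05 a.u.) at bout onset + `event_lag`; an
  offset-locked triangular ramp sets the sign of the pre-offset trend.
  The shared artifact is low-pass (1 Hz) filtered Gaussian noise; the
  white-noise draw occurs even at zero amplitude so that sessions with
  and without artifact are sample-for-sample comparable at a fixed seed.
* **Aligned trials** (`simulate_aligned_trials`) carry band-limited
  Gaussian noise (zero-phase Butterworth, 1 Hz corner, SD 0.3 z by
  default) plus an optional step and/or linear trend. The 1 Hz bandwidth
  reflects what z-scored sensor traces look like after the pipeline —
  calcium kinetics of hundreds of milliseconds put essentially all signal
  power below a few Hz — and it is what makes the consecutive-window rise
  rule usable (see calibration above).
* **Stimulation.** Response in ΔF/F units: an elevation boxcar over
  [0.3, 1.2) s post-onset, a linear suppression ramp reaching its full
  depth at the final stimulated sample, and an exponential rebound from
  offset; raw signal = bleach·(1 + response + noise). For 3-min epoch
  protocols an open-field velocity trace is scaled by configurable ON/OFF
  factors (defaults 0.6 / 1.3: suppression during stimulation, rebound
  after — the `KREMEN1_LIKE` phenotype; a `CALB1_LIKE` preset inverts
  the response shape).

What passing tests show — and do not. Closure and recovery tests prove
the pipeline implements its own definitions correctly and recovers known
parameters under the generator's assumptions (shared linear artifact,
band-limited noise, sparse transients). They cannot certify performance
on real recordings, where artifacts are not exactly linear across
channels, noise spectra differ, and sensors saturate.

Percentile baselining under large artifacts: because F₀ is a low
percentile, a zero-mean artifact of SD σ drags F₀ down by ≈1.28 σ and
thereby inflates all ΔF/F by a factor ≈ F/(F − 1.28σ). At artifact SD
0.05 a.u. on a baseline near 1.15 a.u. this is ~6 %; at SD 0.08 it
exceeds 10 %. This is a property of percentile baselining itself, not of
the referencing step, and bounds how large an artifact the behavior-mode
pipeline can tolerate while preserving amplitudes.

## Numerical conventions

* Time is session-relative seconds, t[0] = 0 after alignment; all event
  windows are half-open [a, b); window indices come from
  ceil((a − t₀)·rate − 1e-6), so on-grid endpoints land exactly.
* Sampled window means of an exponential are compared against the closed
  form of the finite geometric series on the grid, which is exact to
  machine precision; the continuous integral differs from the sampled
  mean by O(Δt/τ) (~3e-5 relative at 1 kHz, τ = 5 s) and is therefore
  not used as an oracle at tight tolerances.
* The per-trial minimum statistic (maximum reduction) is biased downward
  under noise — the expected minimum of n noise samples is ≈ −σ·Φ⁻¹-order
  — so noisy recovery is validated against the statistic evaluated on the
  generator's realized noisy response (and, in unit tests, against a
  brute-force order-statistic simulation), not against the noiseless
  amplitude. A `summarize_stim_trials(..., on_mean_trace=True)` mode
  computes the minimum on the trial-mean trace instead, which reduces the
  bias by ~√n_trials.
* Problem sizes in the test suite (60–600-s sessions at 100–250 Hz,
  20–1000 replicates) are the package's chosen desk-scale study
  conditions; they preserve the ratios (window length × rate, bouts per
  session, trials per session) that the statistics depend on.

## Known limitations

* The behavior-mode pipeline assumes the artifact enters both channels
  linearly; multiplicative or saturating artifacts are out of scope.
* `AnalysisParams` carries one threshold set per concept; the immobility
  merge/duration rules share the ambulation values (the assays use the
  same 0.5-s constants).
* The rise-time detector's error control is the printed 5-step rule only;
  its false-positive rate depends strongly on the noise spectrum of the
  input (see calibration) and should be re-measured before use on data
  with different filtering.
* EthoVision parsing, video pixel-change computation, lock-in
  demodulation, and group-level inferential statistics are outside the
  package; it consumes demodulated traces and velocity/motion-index
  series and emits per-session metrics.
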