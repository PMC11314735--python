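# Methods

## Problem and pipeline

A single smartphone worn at the posterior pelvis records ten channels at a
nominal 60 Hz: system time, linear acceleration (mediolateral X, vertical Y,
anteroposterior Z), angular velocity about the same axes, pitch, roll, and
azimuth (heading about the vertical axis, wrapped into [0°, 360°)). The task
is to recover the start and end times of the six L test subtasks — stand-up,
first 90° turn, first 180° turn, second 90° turn, second 180° turn,
sit-down — for lower-limb amputees, whose movement patterns defeat
rule-based segmenters tuned on able-bodied gait.

The pipeline treats segmentation as per-sample binary classification, one
model per subtask, followed by run extraction. Stages and their
assumptions:

### Signal conditioning

* **Azimuth wrap correction.** Any consecutive heading change larger than
  the jump threshold (default 10°) is replaced by its nearest mod-360°
  equivalent and the correction is propagated. This is the standard phase
  unwrap with a 360° period and agrees with `numpy.unwrap(period=360)`
  everywhere, provided the true turn rate stays below the threshold per
  sample (10° per sample = 600°/s at 60 Hz, far above human turning). The
  output is continuous and unbounded. A `literal` mode that nulls the jump
  entirely (losing within-sample rotation) is kept for fidelity
  experiments. The correction is idempotent and changes samples only by
  multiples of 360°.
* **Zero-lag low-pass.** Fourth-order Butterworth, 4 Hz cut-off, applied
  forward and backward (`filtfilt`) so event timing is not phase-shifted;
  the effective magnitude response is the squared single-pass response.
  Edges are mirror-padded with 3×order samples, so series must be longer
  than 12 samples. Only acceleration and angular-velocity channels are
  filtered — pitch/roll/azimuth are already smooth orientation estimates
  and filtering would soften turn onsets.
* **Magnitude normalization.** Each filtered motion channel is divided by
  its per-trial peak absolute value (range ⊆ [−1, 1]); all-zero channels
  pass through. Orientation channels keep physical units, which matters:
  a 180° turn spans a fixed azimuth range regardless of how fast the
  participant moves.
* **Time offsets.** Video-derived annotation clocks are aligned by adding a
  scalar offset to the trial's timestamps; deriving the offset is out of
  scope.

Order of operations: unwrap first (as the narration of the source pipeline
implies), then filter, then normalize.

### Subtask data ranges

Each subtask's plausible location is a fixed percent range of trial length
(stand-up 0–31%, first 90° turn 10–42%, first 180° turn 36–63%, second 90°
turn 61–84%, second 180° turn 72–97%, sit-down 76–100%). Ranges are
interpreted on sample counts (equivalent to percent of test time under
uniform sampling), rounded outward (floor/ceil) so they never shrink, and
are configurable. If a ground-truth event escapes its range the extraction
*raises* rather than silently clipping — the ranges were derived from a
specific cohort and a violation means they need re-estimation. A
half-sample tolerance absorbs the gap between the last sample and the
nominal recording end. Occurrence labels are inclusive at both interval
ends.

### Features

For every sample, eight statistics over the trailing 24-sample window of
each of the nine signals (72), the nine instantaneous values, and system
time: 82 columns. Conventions, chosen where the source is silent:

* "variation" = sample variance (n−1); "std" = its square root;
* skewness/kurtosis are population-standardized third/fourth central
  moments, kurtosis as excess (normal window → 0);
* constant windows score 0 on every dispersion/shape statistic (no NaNs);
* rows before the first full window repeat the first full-window values, so
  sample 0 (stand-up onset) keeps a feature row and labels stay aligned.

Reversed-direction analysis mirrors the dataset in time *before*
windowing, which moves each sample's informative context from behind it to
ahead of it — useful for subtasks near the trial end. Reversal is an exact
involution; the time column is re-reflected about the slice's own span so
it stays strictly increasing and keeps its clock origin (a deliberate
deviation from reflecting onto a zero origin, which would break the
involution on the time column).

Feature ranking uses the two-group one-way ANOVA F statistic
(`f_classif`), computed **inside** each cross-validation fold on training
rows only, and on the full training set for final models — never on test
participants. Constant features rank last with score 0 and a warning; ties
keep schema order (stable sort).

### Classifier and transitions

One `RandomForestClassifier` per subtask: Gini criterion, unrestricted
depth, seeded, single-threaded. The grid search is exhaustive over forest
size × feature count × direction (default 6 × 7 × 2 = 84 configurations),
scored by mean k-fold cross-validated sample accuracy with folds
partitioning participants (never samples — within-trial correlation would
otherwise leak). Ties break toward the smaller model: fewer trees, then
fewer features, then forward. Class imbalance is handled only by the range
extraction, as in the source protocol; `class_weight` is exposed but off by
default.

Per-sample predictions (always returned in forward order) become one
(start, end) pair: median smoothing with a 5-sample kernel, then the
longest contiguous positive run, earliest run on ties; an empty result
raises a "no event detected" error, which evaluation counts as a failed
boundary. The smoothing kernel is the artifact's own choice — the source
never states how per-sample outputs became timestamps.

### Evaluation

* **Average step time** = mean interval between consecutive ground-truth
  foot strikes over the whole trial ("step", not stride: consecutive
  strikes of either foot).
* **Accuracy_AD** = percent of test participants with
  |t_pred − t_gt| **<** (strict) their own step time, per subtask boundary;
  missing events fail.
* **Sample-level accuracy/sensitivity/specificity** are pooled over test
  samples per subtask (per-participant results are also retained);
  one-class truths flag the undefined metric as NaN.
* **Leave-one-out**: one fold per amputee participant; every fold's
  training set is all able-bodied trials plus the other amputees' trials;
  grid search and feature ranking run inside the fold's training set only.
  Fold bookkeeping (held-out id, training ids, chosen configs) is recorded
  for leakage audits.

## Synthetic data

No L test IMU data are public, so `ltest.synthetic` generates trials whose
ground truth is exact by construction. A trial is eleven phases (sit idle,
stand-up, four walks, four turns, sit-down). The generator targets signal
*structure*, not validated biomechanics:

* **Heading**: smoothed-trapezoid ramps of +90°, +180°, −90°, +180°
  (net +360°), rate-modulated at the step frequency because people turn in
  discrete pivot steps, with per-turn random modulation depth, phase and
  ramp sharpness (motor execution variability). Emitted azimuth is wrapped
  into [0°, 360°) to exercise the unwrap stage.
* **Gait**: continuous from the first walk through the last turn (L test
  walking does not pause), sinusoids at step frequency (vertical/AP
  acceleration, pitch sway) and stride frequency (ML acceleration, roll and
  yaw sway — the pelvis rotates once per stride), all scaled by a smooth
  per-step amplitude envelope (sd 0.15, the stride-to-stride variability of
  real gait). Yaw sway fades inside turns, where the pivot-step modulation
  *is* the pelvic oscillation. Foot strikes sit at vertical-acceleration
  peaks, so mean step time = 1/cadence exactly.
* **Gyroscopes** are the analytic time derivatives of the orientation
  channels (rate and angle are mutually consistent), plus short
  alternating-sign heel-strike transients (~35°/s, 0.12 s) that the 4 Hz
  filter largely removes — as in real pipelines.
* **Stand-up/sit-down**: single smooth pitch hump of ±30° with a ±2 m/s²
  vertical-acceleration pulse; sit-down is the sign-opposite of stand-up.
* **Noise**: independent Gaussian per channel (defaults ~0.05 m/s²
  accelerometer, 1°/s gyro, 0.3–0.5° orientation).
* **Cohorts**: able-bodied participants contribute 5 trials, amputees 1;
  amputee movement durations ×1.25 and cadence ×0.8; every phase duration
  and the cadence get ±8% uniform per-trial jitter. Defaults place every
  ground-truth event inside its percent range with margin; totals are
  ~30.5 s (able) / ~37.6 s (amputee).

What a green test therefore establishes: the pipeline recovers transitions
whose signatures (heading ramps, pitch humps, gait onset/offset) are
present and roughly of real magnitude, under sensor noise and moderate
inter-participant variability. What it does not establish: performance on
real amputee gait (asymmetry, prosthetic compensations, magnetometer
disturbance of azimuth, annotation error), which is why the published
performance tables are treated as schema references, not reproduction
targets.

### A note on the turn-feature ranking

On real recordings, azimuth range and azimuth standard deviation lead the
ANOVA-F ranking for every turn subtask. On this simulator the vertical-gyro
peak statistics score comparably and often slightly higher for the 180°
turns: when the gyro is exactly the derivative of a clean heading and both
are band-limited, windowed rate peaks and heading spans carry equivalent
information, and their F ordering hinges on second-order variance structure
rather than on the real-world asymmetries (fused-heading stability versus
raw-gyro artifacts) that favor azimuth in practice. Azimuth range/std are
consistently within the top five for every turn subtask here; the stricter
first-and-second property is asserted in the acceptance suite and currently
fails for three of the four turns — kept red deliberately rather than
tuning generator amplitudes until the ranking flips.

## Numerical and degenerate-input choices

* Percent-range bounds: floor(lower·N/100), ceil(upper·N/100), clipped.
* Constant feature windows → 0 moments; constant features → F = 0 + warning.
* `np.mod` seam: azimuth exactly at 360° after float rounding maps to 0°.
* Median smoothing kernel 5; runs tie-break to the earliest.
* Grid-search tie-break: fewer trees, fewer features, forward.
* All randomness flows from explicit integer seeds (cohort jitter, noise,
  fold shuffling, forests); identical seeds give bit-identical results.

## Scaled test sizes

The acceptance tests shrink *compute*, never thresholds: trials are
time-scaled (×0.25–0.35, keeping 60 Hz and the 24-sample window; every
event keeps its fractional position, so the percent ranges still apply) and
the inner cross-validation uses 2 folds. Full-size runs reproduce the same
100% clean-cohort boundary recovery but take ~19 minutes per leave-one-out
run on one CPU.

## Known limitations

* The simulator's gait is sinusoidal with amplitude variability only; no
  asymmetric prosthetic gait, no azimuth drift or magnetic disturbance.
* Table-range re-estimation for new cohorts is not implemented (extraction
  raises instead).
* One model per subtask; boundary-specific models (separate start/end
  classifiers) are not implemented — the grid may therefore compromise
  between the two boundaries of a subtask.
* Sample-level metrics are pooled across participants; a
  per-participant-averaged variant is derivable from the retained
  per-participant results but not reported by default.
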