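# Methods

This note documents the models and procedures `pshkit` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic validation does and does not
establish.

## Data model and conventions

All series are per-patient, per-signal trends (heart rate in bpm,
respiratory rate in breaths/min, systolic blood pressure in mmHg) on a
nominal 0.5 Hz grid, with timestamps in seconds from *time zero* — the
first recorded sample. Every interval in the package (analysis
windows, hourly segments, episodes, trend windows) is half-open
`[start, end)` in those record-relative seconds, so no sample is ever
counted by two abutting windows. Window statistics are exact: the
population variance (divide by *n*, well-defined at n = 1 and
negligibly different from the sample variance on the ~300-sample
windows the detectors use) and the even-*n* median as the midpoint of
the two central order statistics.

Artifact filtering removes samples outside a closed plausibility range
per signal. The heart-rate range [30, 250] bpm is the adult normal
reference range; the respiratory-rate [4, 80] and systolic-pressure
[40, 300] defaults are this package's choices (no published range was
adopted for them) and are configurable. Bounds are inclusive: a value
exactly at a bound is physiologically plausible and kept.

CSV dialects: vitals `patient_id,signal,timestamp_s,value`; episodes
`patient_id,start_s,end_s,source`. Rows with unparseable numerics are
dropped with a logged count; exact duplicate timestamps collapse to
the last-read value (bedside-monitor exports differ in how they handle
retransmissions, and last-write-wins is the least surprising rule).

## Hourly high-resolution Clinical Feature Scale (hrCFS)

Each hour `[3600·h, 3600·(h+1))` of each filtered signal is divided
into 5-minute rolling windows with a 2.5-minute step — start offsets
0, 150, …, 3450 s, i.e. exactly 24 windows. The 24th window would
overrun the hour, so it is truncated at the hour boundary: this keeps
the stated 24 values per hour without cross-hour leakage, which the
method description leaves open. The maximum of the per-window maxima
summarises the hour (for a fully covered hour this equals the plain
hourly maximum; the windowed construction is retained for fidelity and
for future per-window outputs) and is scored 0–3 by the Clinical
Feature Scale cut-points:

| signal | 1 at | 2 at | 3 at |
|---|---|---|---|
| HR (bpm) | 100 | 120 | 140 |
| RR (/min) | 18 | 24 | 30 |
| SBP (mmHg) | 140 | 160 | 180 |

The three subscores sum to the hourly composite (0–9). Hours are
record-relative, not clock-aligned. A subscore is withheld when the
signal's hourly coverage (present / expected 0.5 Hz samples) falls
below `min_coverage` (default 0.5 — the method description is silent
on missingness, so the threshold is exposed); the composite requires
all three subscores.

Because scoring applies to an extreme-value statistic over ~1800
samples, even quiet hours of noisy physiology can score 1–2 points:
the hrCFS measures worst-case excursions, not typical levels.

## Expert-system episode detector

Three rules on each 10-minute sliding window of heart rate (2-second
step, window grid anchored at time zero; anchoring is unstated in the
method description): minimum > 95 bpm, median > 104 bpm, variance >
37 bpm², all strict inequalities. A window satisfying at least two of
the three votes positive; empty windows (data gaps) vote negative
rather than abstain, so dropouts cannot create positives. Every
sample takes the maximum vote over its covering windows. Runs of
positive samples become episodes `[t_first, t_last + one sampling
period)`; a sampling gap > 60 s splits a run (a dropout longer than
the merge gap should not silently bridge an episode); episodes with a
break strictly shorter than 60 s are merged.

The dense stepping demands efficient exact rolling statistics: on a
gapless uniform grid whose step and width are sample-period multiples,
full windows are computed with pandas' rolling kernels (order-
maintaining sliding median, O(N log m)); truncated trailing windows
and non-uniform series are recomputed per window. Both paths return
exact statistics — no approximate medians.

`grid_search_rules` re-derives (a, b, c) against an annotated episode
set by evaluating every triple end to end and maximising range-based
F1. "Optimising precision and recall" does not name a scalarisation,
so the balanced harmonic mean is this package's choice; ties break
toward larger thresholds (the more conservative rule set).

## SVM episode detector

Features mean, standard deviation, minimum, maximum, and median are
extracted from 10-minute rolling windows with a 2.5-minute step (the
larger step limits redundancy among training windows). A window fully
contained in an annotated episode is a positive example; a window
disjoint from every episode is negative; a window straddling an
episode boundary belongs to neither regime and is excluded —
"inter-episode baseline" does not define partial-overlap handling, so
exclusion is this package's choice. Features are standardised to the
training mean and standard deviation (a zero-variance feature gets
unit scale with a warning) and fit with an RBF-kernel SVC at the
ecosystem defaults: C = 1.0, kernel width `gamma = 1/(n_features ·
feature variance)`, no class rebalancing (class weights are exposed in
the configuration). Training is deterministic given the seed and data
order. The model serialises to a versioned joblib archive carrying the
classifier, standardisation, geometry and seed, and reloads to
identical predictions.

Prediction reuses the training window geometry (600 s / 150 s) rather
than the expert system's 2-second step: the prediction step size is
unstated, and matching the training geometry keeps the feature
distribution the classifier sees identical to the one it was fit on.
Window predictions fuse to sample labels by the same maximum rule as
the expert system, and episode assembly/merging is shared.

## Burden, trends, summaries

The burden score of a frame is the fraction of it covered by episodes
(episodes clipped to the frame); it is bounded in [0, 1] and additive
over a partition of the frame. Trends evaluate the burden over
consecutive non-overlapping 12-hour windows from time zero — 28
points over 14 days — with a final partial window scored over its
actual length. First-14-day summaries clip episodes to [0, 14 days)
and report count, mean clipped duration in minutes (undefined at zero
episodes), and overall burden. Group contrasts use Cohen's d with the
pooled sample standard deviation (undefined marker when it is zero).
Cross-patient trend bands use the t-distribution interval
mean ± t·sd/√n (the interval construction behind such bands is
typically unstated; windows with fewer than two patients report the
mean only). Aggregating hourly hrCFS composites into 12-h windows,
where needed, defaults to the mean (configurable), since the
aggregation is likewise unstated.

## Range-based precision and recall

Detected (P) and annotated (R) episodes are interval sets, so each
detected episode P_i is scored by its overlap proportion
|P_i ∩ ∪R| / |P_i| and precision is the mean over the N_p detections;
recall mirrors this over the N_r annotations. Only the outer averages
are pinned down by the published formulas; the inner per-episode
function used here is the simplest member of the Tatbul et al. family
(flat positional bias, no existence bonus, cardinality factor 1) and
is pluggable for the other members. Under this variant
Precision(R, P) = Recall(P, R) exactly. When the set a metric
averages over is empty the metric is *undefined* (None), not 0 or 1 —
averaging conventions on emptiness are otherwise arbitrary.

## Synthetic cohort generator

Each signal's baseline is a stationary Gaussian AR(1) process (lag-1
correlation 0.95 at 0.5 Hz; marginal sd HR 5, RR 2, SBP 8 around
means 80 / 14 / 120) — the simplest autocorrelated stand-in for real
trend dynamics. Episode start times follow a Poisson process at
4/day; durations are log-normal, moment-matched to mean 42 min / sd
16 min and truncated to [2 min, 2 h]; candidates that would overlap,
leave an inter-episode gap under 2 minutes, or overrun the record are
rejected. During an episode core every signal's mean rises by its
delta (HR +35 bpm, RR +12, SBP +45 — simultaneous multi-channel
elevation, as in PSH phenomenology) with 30 s linear onset/offset
ramps and a doubled noise sd inside the core. Ground truth records
the un-ramped cores: detectors are scored against the sustained
elevation, and the ramp seconds are small relative to episode
durations. An optional artifact rate injects out-of-range spikes for
exercising the filter. Cohorts derive independent per-patient
sub-seeds from one master seed; identical seeds are bit-identical.

The reported annotation statistics are internally tense — a standard
deviation of 16 min is hard to reconcile with an observed range of
3–206 min — so the simulator matches the stated moments and the
qualitative 2 min–2 h range rather than the extremes.

What the generator does **not** emulate: circadian rhythm,
cardiorespiratory coupling, medication effects, realistic artifact
morphology, missing-data structure, or between-patient heterogeneity
in baseline physiology. Passing the synthetic recovery tests therefore
shows the pipeline is internally consistent and recovers the episode
process it models; it does not establish clinical performance.

## Known limitations and measured behaviour

* Both detectors inherit a *boundary smear* from max-fusion: one
  positive 10-minute window labels all of its samples, so detected
  episodes extend past the true edges. The expert system's median
  rule fires only when a window is majority-episode (~58 % overlap
  given the default synthetic regimes), bounding the smear near half a
  window per side; on the default 14-day synthetic cases this yields
  range recall 1.0 and range precision ≈ 0.81–0.83.
* The SVM's decision boundary is learned only from fully-inside and
  fully-outside windows, so boundary-straddling windows are
  extrapolation. Their maximum feature matches the positive class
  (any episode sample sets the window max) and their mixture standard
  deviation exceeds even the positive class, so windows with as little
  as ~15 % episode overlap are classified positive. The smear then
  approaches a full window per side, and measured range precision on
  the default synthetic cases is ≈ 0.70–0.72 (recall 1.0) — the
  corresponding ≥ 0.8 check in the acceptance suite fails and is left
  failing deliberately; see the per-window positive rates by overlap
  fraction in the module's behaviour under default hyperparameters.
  Post-hoc boundary trimming or calibrated decision thresholds could
  reduce the smear but are out of scope.
* Problem sizes: the test suite's full-scale run uses 2 cases + 2
  controls × 14 days at 0.5 Hz (604 800 samples per signal), the
  scale the methods are designed for; property-based oracles run on
  small randomised instances where brute force is exact.
* The hrCFS hourly maximum is sensitive to any surviving artifact
  inside the plausibility range; only range-based filtering is
  implemented.
* Grid search evaluates the full Cartesian grid with window statistics
  computed once; it does not exploit monotonicity of the rules in the
  thresholds, which would allow pruning.
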