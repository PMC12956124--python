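# pshkit

Automated detection and quantification of **paroxysmal sympathetic
hyperactivity (PSH)** from continuous bedside vital-sign trends.

PSH is a syndrome of recurrent, abrupt-onset sympathetic surges —
tachycardia, hypertension, tachypnea — seen in a large fraction of
critically ill traumatic brain injury patients. Clinical recognition is
subjective and often delayed, while the data that define the syndrome
(0.5 Hz heart-rate, respiratory-rate, and systolic-blood-pressure
trends) stream continuously from standard monitors. `pshkit` implements
three complementary quantification methods over those trends, plus the
evaluation and simulation machinery needed to exercise them end to end
without any patient data:

1. **hrCFS** — an hourly high-resolution Clinical Feature Scale.
   Each signal is scored 0–3 against the Clinical Feature Scale
   thresholds (e.g. HR: <100 / 100–119 / 120–139 / ≥140) applied to the
   hour's maximum, taken as the max over 24 five-minute rolling windows
   (2.5-minute step). The composite over HR + RR + SBP ranges 0–9.
2. **Expert-system (ES) episode detector** — sliding 10-minute windows
   of heart rate with a 2-second step, voted by three rules
   (HR min > 95, HR median > 104, HR variance > 37 bpm²) with 2-of-3
   voting; per-sample labels are the max over covering windows;
   positive runs become episodes, and episodes separated by < 1 minute
   are merged. `grid_search_rules` re-derives the thresholds from
   annotated data by maximising range-based F1.
3. **SVM episode detector** — mean/sd/min/max/median features from
   10-minute rolling windows (2.5-minute step), standardised and fed to
   an RBF-kernel support-vector classifier trained on windows inside
   annotated episodes vs. inter-episode baseline; prediction and
   episode assembly mirror the rule-based path.

Episode output is summarised by the **burden score** — the temporal
density of episodes in a frame,

    B = (1/T) · Σₙ duration(εₙ),

so 2 cumulative hours of episodes in a 4-hour frame give B = 0.5 —
evaluated over consecutive 12-hour windows from time zero (28 points
per 14 days), plus first-14-day episode counts/durations and Cohen's d
between patient groups. Detections are scored against annotations with
**range-based precision/recall** (after Tatbul et al.): each detected
episode contributes its overlap fraction with the annotated set
(averaged over detections → precision), and symmetrically for recall.

A seeded synthetic cohort generator (AR(1) baseline physiology with
recurrent log-normal-duration elevation episodes and ground-truth
intervals) makes every stage testable and reproducible.

## Worked example

Run the demo pipeline — simulate 2 PSH cases and 2 controls for 14
days at 0.5 Hz, score the hrCFS, run both detectors (the SVM is
trained on the first simulated case's ground-truth annotation and
applied cohort-wide), compute burden trends, and evaluate against
ground truth:

```bash
pshkit demo --out-dir demo/ --seed 17
```

prints

```
es: mean case precision 0.815, recall 1.000, case-control burden difference 0.136
svm: mean case precision 0.712, recall 1.000, case-control burden difference 0.155
```

Recall 1.0 means every ground-truth episode is fully covered by a
detection; precision below 1.0 reflects each detector's boundary smear
(a positive 10-minute window labels all of its samples, so detected
episodes extend a few minutes past the true edges). Both detectors
separate cases from episode-free controls: the mean detected 14-day
burden difference is positive, and the controls' median detected
burden is 0.

The demo directory then holds the CSV/JSON artifacts, e.g. hourly
hrCFS scores (`hrcfs.csv`):

```
patient_id,hour_index,hr_score,rr_score,sbp_score,composite,coverage
case01,0,2,3,3,8,1.0
case01,1,3,3,3,9,1.0
case01,2,0,1,1,2,1.0
```

(hours containing an episode score high; quiet hours score low) and
detected episodes (`episodes_es.csv`):

```
patient_id,start_s,end_s,source
case01,2716.0,6582.0,es
case01,39456.0,42182.0,es
```

The individual stages are available as subcommands — `simulate`,
`hrcfs`, `detect-es`, `train-svm`, `detect-svm`, `burden`,
`summarize`, `evaluate` — and as plain library functions
(`pshkit.detect_episodes_es`, `pshkit.burden_score`, …).

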