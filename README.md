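# egmdur

Automated estimation and 3-D visualization of **intracardiac electrogram (EGM)
duration** for substrate mapping in ischemic ventricular tachycardia (VT).

Prolonged bipolar EGM duration is a surrogate for slow myocardial conduction,
the mechanistic core of scar-related reentry. During substrate-based VT
ablation, electrophysiologists annotate EGM characteristics by hand — slow,
subjective work on maps that now contain thousands of points. `egmdur`
implements an automated detector and the segment-level validation machinery
around it, for signal-processing researchers and EP-lab engineers working
with high-density electroanatomic maps.

## The algorithm

Each filtered bipolar EGM *x(t)* (30–250 Hz bandpass, 50 Hz notch, zero
phase) is transformed into an activity envelope by a **sliding
standard-deviation window**: at every sample, the population SD of the
surrounding *w* ms of signal,

```
SD_w(t) = std( x[t − w/2 … t + w/2] )
```

Onset and offset are the first and last samples where the SD-curve reaches a
fixed fraction θ of its own maximum,

```
onset  = min { t : SD_w(t) ≥ θ · max SD_w }
offset = max { t : SD_w(t) ≥ θ · max SD_w }
```

and the EGM duration is `offset − onset`. Because θ is relative to the
curve's maximum, the estimate is independent of signal amplitude — the same
rule works in dense scar (< 0.2 mV) and healthy myocardium (> 1.0 mV).
Durations strictly greater than a cutoff *c* flag abnormally prolonged
activity. The clinically validated operating point is **w = 40 ms,
θ = 15 %, c = 70 ms**.

For validation, maps are divided into the AHA 17-segment model from three
anatomical landmarks (apex, base center, septal direction); per segment, the
mean duration is compared against the segments in which VT-terminating
ablation was performed, via the **diagnostic odds ratio**
`DOR = (TP·TN)/(FN·FP)` with a log-normal 95 % CI. A grid search over
w ∈ 10–45 ms, θ ∈ 10–50 %, c ∈ 60–80 ms selects the parameter triple with
the maximum DOR.

Because clinical map exports are proprietary, the package ships a synthetic
cohort generator (`egmdur.synthetic`) producing full left-ventricular maps
with scar architecture, class-specific EGM morphologies (sharp healthy
deflections, fractionated border-zone potentials with low-amplitude late
components, low-voltage dense-scar activity) and ground-truth onsets/offsets.

## Worked example

```python
from egmdur import (CohortSpec, DurationParams, generate_cohort,
                    map_durations, summarize_segments, cohort_statistics)

maps = generate_cohort(CohortSpec(n_patients=4, points_per_map=1000, seed=42))
durations = map_durations(maps[0])
print(durations.head(3))

summary = summarize_segments(maps[0], durations, cutoff_ms=70.0)
cs = cohort_statistics(maps, DurationParams(40.0, 0.15, 70.0))
```

prints per-point detections,

```
point_id  onset_ms  offset_ms  duration_ms  prolonged  degenerate
  p00000     166.0      232.0         66.0      False       False
  p00001     127.0      265.0        138.0       True       False
  p00002     167.0      233.0         66.0      False       False
```

a per-segment summary (segment 4 here carries dense scar — mean voltage
0.10 mV, saturated duration; its halo neighbors 3 and 5 are border zone with
means ≈ 115–136 ms; segment 8 is healthy at 59 ms and correctly *not*
abnormal despite carrying a spillover lesion),

```
segment  n_points  mean_duration_ms  mean_voltage_mv voltage_class  ablated  abnormal
      3        58        114.706897         0.629929        border     True      True
      4        61        382.918033         0.104004         dense    False      True
      5        51        136.078431         0.584809        border     True      True
      8        60         59.266667         2.107185       healthy     True     False
```

and the pooled cohort validation

```
pooled 2x2: tp=15 fn=8 fp=9 tn=36
DOR 7.50 (95% CI 2.43-23.14), sensitivity 65.2%, specificity 80.0%
```

i.e. on this small synthetic cohort a segment with mean duration > 70 ms has
7.5-fold higher odds of having been ablated than a normal-duration segment.

The same pipeline is scriptable from the shell:

```bash
egmdur simulate --patients 16 --points 2000 --seed 7 --out cohort/
egmdur report --inputs cohort/synth00 --inputs cohort/synth01 --out results/
egmdur grid --inputs cohort/synth00 --w 10:45:5 --theta 0.10:0.50:0.05 --c 60:80:5 --out surface.csv
```

`egmdur report` writes per-point CSVs, 17-segment bull's-eye plots (duration
and voltage, ablation markers overlaid), optional colored PLY meshes, and a
machine-readable `report.json`.

scikit-learn users can drop the detector into pipelines via
`egmdur.EgmDurationEstimator` (a transformer over trace matrices) and
`egmdur.DorGridSearch` (fits the three parameters on a cohort of maps).

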