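# pivotshift

Desk-scale analysis of smartphone-gyroscope recordings of the pivot-shift
knee exam: simulate study-shaped cohorts, segment each 5-s X-axis capture
into flexion / extension / pivot phases, extract morphological features of
the pivot (joint-reduction) region, quantify rater reliability with
intraclass correlation coefficients, grade knee laxity from KT-1000
side-to-side differences, and classify laxity grade with a two-stage
(speed-class, then grade-within-class) machine-learning pipeline.

## Layout

| module                    | role |
|---------------------------|------|
| `pivotshift.model`        | domain types (recordings, segments, features, grades) |
| `pivotshift.simulate`     | synthetic recordings and cohorts with ground truth |
| `pivotshift.io`           | CSV recordings, JSON session manifests, feature tables |
| `pivotshift.preprocess`   | axis selection, [0,1] normalization, peak detection, segmentation, pivot extraction |
| `pivotshift.features`     | characteristic vectors and the four pivot features (`sd_nv`, `max_ov`, `range_plus_mean_ov`, `mean_square_ov`) |
| `pivotshift.reliability`  | ICC(1) / ICC(2,1) / ICC(3,1) from ANOVA mean squares, intra-/interobserver analyses, Landis–Koch labels |
| `pivotshift.grading`      | KT-1000 difference → laxity grade 0–3; speed-class binning |
| `pivotshift.classify`     | per-grade train/test split, raw-signal baseline, two-stage SVM → decision-tree classifier, micro-averaged evaluation |
| `pivotshift.cli`          | `psm` command-line front end |

## CLI

```sh
psm simulate --config cohort.yaml --seed 42 --out run/   # session.json + recording CSVs + truth.csv
psm features --session run/ --out features.csv           # one row per (recording, maneuver)
psm icc --session run/ --mode inter --out icc-report.json
psm grade --left-mm 9 --right-mm 6                       # -> grade 1 (3 mm difference)
psm train --features features.csv --stage1-method svm --stage2-method dt \
    --seed 1 --out model/                                # model.joblib + eval-report.json
psm evaluate --model model/model.joblib --features features.csv --out eval.json
psm predict  --model model/model.joblib --features features.csv
```

A YAML config can override any default (`grade_counts`, `raters`,
`repeats`, `noise_sd`/`noise_frac`, `peak.*`, `grading.class_edges`,
`icc.*`, `classify.*`); unknown keys are rejected by name.  All randomness
flows from a single seed, so repeat runs are byte-identical.

## Conventions

* Time is measured in centiseconds; at the nominal 100 Hz sampling rate a
  sample index equals its time in cs.
* Sample intervals are half-open `[start, end)`, 0-based.
* `sd_nv` is the population (divide-by-N) standard deviation.
* Normalization to [0, 1] is per whole recording, so normalized pivot
  values are comparable across a capture's maneuvers.
* Reported ICC estimates are clipped to [0, 1]; the raw value is kept in
  the result object.
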