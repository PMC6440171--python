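# kinesym

Sensor-based quantification of Parkinsonian symptomatology during activities
of daily living (ADL), plus the control-referenced statistical analysis of
which symptoms predict task failure.  The package turns full-body inertial
recordings (17 IMUs: 3-axis gyroscope in deg/s, 3-axis accelerometer in
m/s²) into per-task symptom levels and runs a purposeful-selection logistic
regression with ROC/Youden cutpoint analysis on the resulting cohort table.
A synthetic-data module generates recordings and cohorts with known ground
truth so the whole pipeline is testable without clinical data.

## Symptom quantifiers

- **Tremor** (`kinesym.tremor`) — hand gyroscopes band-passed to 3.5–7.5 Hz,
  5 s windows; a window is tremulous when the contiguous band holding 68% of
  spectral power around the dominant frequency is narrower than 2 Hz; window
  amplitudes (in-band power) are summed over windows and hands.
- **Dyskinesia** (`kinesym.dyskinesia`) — 0.5–4 Hz band-limited energy of the
  non-task-involved sensors (sitting excludes arms, standing/walking excludes
  legs), averaged per body segment in 1 s windows with Q3 + 1.5·IQR outlier
  capping; the task score is the summed segment mean, an energy per second.
- **Freezing of gait** (`kinesym.freezing`) — freeze-index ratio of 3–8 Hz to
  0.5–3 Hz accelerometer power on the 7 gait sensors; a step is frozen when
  at least 4 sensors exceed the threshold; reported as percent time frozen.
- **Bradykinesia** (`kinesym.bradykinesia`) — mean per-cycle maximal angular
  velocity of the 10 s forearm pronation–supination (RAM) trial.

## Statistics stage

`kinesym.cohort_stats` provides LID-presence classification against a
control mean + 1 SD threshold, per-task success criteria (control mean +
2 SD for time and error count), Kruskal-Wallis group comparison,
maximum-likelihood logistic regression (IRLS, with separation detection),
purposeful variable selection (significance screen plus ≥15%
change-in-estimate confounder retention), ROC/Youden cutpoints, and
nearest-in-time (±10 min) pairing of sequential assessments with tasks.

## Command line

```sh
kinesym simulate --scenario scenario.yaml --out study/   # synthetic study
kinesym extract  --config extract.yaml                   # symptom table
kinesym analyze  --config analyze.yaml                   # stats bundle
kinesym report   --results study/results/results.json    # text report
```

A study scenario (`kind: study`) controls cohort sizes, tasks, planted
signal amplitudes and performance models; see
`kinesym.synthetic.STUDY_DEFAULTS` for the schema.  An extraction config
needs `manifest` (CSV with participant_id, task_id, posture, start_s, end_s,
recording) and `out`; an analysis config needs `cohort` (covariate CSV),
optionally `symptoms` (extraction output) and `out_dir`, plus
`alpha_enter` / `alpha_stay` / `confound_pct` overrides.

All file formats are plain CSV (wide recordings with
`<sensor>_<gyro|acc>_<x|y|z>` columns, written at full float precision) and
results are JSON plus a text report; every threshold and configuration value
used is echoed into the report.

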