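# tcore — wearable core-body-temperature estimation

`tcore` estimates core body temperature (T_C) each minute from the signals a
wearable arm device can actually measure — heart rate, skin temperature,
skin relative humidity and ambient temperature — using a scalar-state
extended Kalman filter (EKF). Core temperature is the physiological quantity
that matters for heat-stress safety, but measuring it directly requires a
rectal probe or an ingestible pill; the point of the estimator is to track it
non-invasively and accurately enough (design criterion: mean absolute error
≤ 0.3 °C) to drive work/rest alerts for people working in the heat.

Because validated human trial data of this kind is not publicly available,
the package also ships a synthetic trial generator: a two-node
(core/skin) thermophysiological model that produces realistic raw sensor
streams and sparsely sampled reference T_C for cohorts of simulated subjects
across four exercise-study templates. Everything downstream — ingestion,
minute aggregation, feature screening, cross-validated training, accuracy
reporting and firmware-style coefficient export — runs identically on
synthetic or real trial CSVs.

## The model in one paragraph

The hidden state is a single scalar, T_C. Each minute the filter runs a time
update (random walk by default, or a learned drift on exogenous features)
followed by sequential scalar measurement updates, one per observation
channel. Each channel models its sensor as a polynomial in T_C (degree ≤ 2
for heart rate, linear for the temperature/humidity channels) fitted to
training data by least squares, with the channel noise variance taken from
the fit residuals. The initial estimate is seeded by a regression whose only
input is biological sex, reflecting the small but consistent resting-T_C
difference between sexes. Training uses leave-one-trial-out (or
leave-one-participant-out) cross-validation; the deployed coefficient set is
the element-wise average across folds, rounded to five decimal places and
re-validated before export.

## Worked example

Run the end-to-end demo (simulate → aggregate → cross-validate → evaluate →
export) on a 6-subject synthetic cohort:

```bash
tcore demo --seed 7 --n-subjects 6 --out demo_out
```

With seed 7 this produces 10 trials (892 paired minutes) and prints, among
other things:

```
"overall": {
  "mae": 0.18251044450611584,
  "rmse": 0.20050434479346166,
  "sem": 0.10823680109866032,
  "pearson_r": 0.9407224742663869,
  "bias": -0.04940281716254589,
  ...
},
"frac_within_0p30": 0.8643497757847534,
"cv": { "mode": "loocv_trial", "candidate": "ekf",
        "mae": 0.2140419209434543, "n_folds": 10 },
"rounding": { "delta_mae": 2.2999559877362463e-05, "passed": true }
```

i.e. a cross-validated MAE of 0.214 °C (within the 0.3 °C criterion), 86 %
of minutes within ±0.30 °C, and a 5-decimal coefficient rounding that moves
MAE by only 2.3 × 10⁻⁵ °C. The output directory contains the cohort CSVs,
the minute tables, the per-axis accuracy reports (`report_by_gt_tc.csv`,
`report_by_hr_zone.csv`, …), Bland–Altman and error-histogram data,
`ekf_params.json` and the firmware coefficient table `coefficients.csv`.

The `examples/` directory holds three short narrative scripts covering the
library API: `01_simulate_and_predict.py` (generator → filter),
`02_cross_validation.py` (fold mechanics and coefficient averaging) and
`03_accuracy_report.py` (overall/binned metrics, Bland–Altman, histogram).
Each stage is also a CLI subcommand (`tcore simulate|aggregate|featurize|
train|predict|evaluate|export`).

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the main computation on a seed-derived 10-subject cohort and writes the
headline quantities. With seed 1 (~6 s on one CPU):

| quantity | value | n |
|---|---|---|
| cv_mae | 0.162824907313466 | 21 trials |
| cv_rmse | 0.18616992833661358 | 21 |
| overall_mae | 0.1495476896374182 | 1900 minutes |
| overall_pearson_r | 0.907557692290314 | 21 |
| frac_within_0p30 | 0.8515789473684211 | 1900 |
| rounding_delta_mae | 1.0804883978671187e-05 | 1900 |

The run is deterministic: the same seed reproduces the file byte-for-byte.
The acceptance test suite (`tests/test_acceptance.py`) additionally checks
metric and Kalman-filter equivalence against independent brute-force
oracles, parameter recovery on a known-coefficient cohort, cross-validation
hygiene on a 52-trial cohort, and rounding robustness.

See `docs/methods.md` for the estimator and generator equations, parameter
tables, numerical choices and limitations.
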