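# Methods

This note documents the estimator, the synthetic trial generator, the
statistical conventions, and the numerical choices, in enough detail to
re-derive what the code computes. Symbols: T_C core temperature (°C), T_sk
skin temperature (°C), t_a ambient temperature (°C).

## 1. The estimator

### 1.1 State model

The hidden state is the scalar T_C with variance P. Per minute:

- **Time update.** `T_C ← T_C + a·u`, `P ← P + q`. By default there are no
  drift features (`a` empty), so the process model is a random walk with
  per-minute variance `q`. When drift features are configured, `a` is fitted
  by least squares of the minute-to-minute change in reference T_C on the
  named exogenous minute features (increments never cross trial boundaries),
  and `q` is the residual variance. Without drift features `q` is the
  variance of the reference-T_C increments, floored at 1e-8 °C².

- **Measurement update.** Sequential scalar updates, one per channel j with
  an available (finite) observation z_j. Each channel models
  z_j = h_j(T_C) + ε_j, h_j a polynomial of degree ≤ 2 (ascending
  coefficients), ε_j zero-mean with variance r_j. Linearizing at the current
  estimate, H = h_j′(T_C):

      K = P·H / (H²·P + r_j)
      T_C ← T_C + K·(z_j − h_j(T_C))
      P ← (1 − K·H)·P        (floored at 1e-12)

  Sequential scalar processing of the channels is algebraically equivalent
  to the joint vector update for linear h_j (verified against a textbook
  joint-update filter to 1e-10 in the tests). Minutes with every channel
  missing pass the state through the time update only.

### 1.2 Seed (initial state)

The initial estimate is `T_C(0) = b0 + b_female·1[sex = female]`, fitted by
OLS of each training trial's first measured reference T_C on a female
indicator. With a single-sex training set the model degrades to
intercept-only with a warning. Initial variance defaults to 0.25 °C²
(≈ ±1 °C at 2 SD), generous enough that the first minutes of data dominate
the seed. Note the estimand is the first *measured* T_C — with sparse
reference sampling this sits slightly above the true starting T_C because
subjects warm up before the first valid reference minute.

### 1.3 Observation-model fitting

Each channel's polynomial is fitted by least squares of the channel's
minute-mean against the reference T_C over all valid training minutes;
degree is a structural choice (default: heart rate degree 2, skin
temperature and skin humidity degree 1). `r_j` is the residual variance with
dof = n − (degree+1), floored at 1e-12. A (near-)constant reference-T_C
range is rejected as degenerate.

Over a realistic 2–3 °C reference range the regressors {1, T_C, T_C²} are
nearly collinear, so the *individual* degree-2 coefficients are not
identifiable even with abundant data — but the fitted polynomial as a
function of T_C on the observed range is, and that is what the filter uses.
The acceptance tests check recovery accordingly: coefficient-wise for
degree-1 channels, function-value and curvature-sign for the degree-2
channel.

### 1.4 Bias offset

An optional additive offset (default 0) is applied to the *emitted*
estimates only, never to the internal state, so an operator can deliberately
bias alerts toward early firing without destabilizing the filter.

### 1.5 Training, cross-validation and export

Folds are leave-one-trial-out (LOOCV, one fold per trial) or
leave-one-participant-out (LOPO, one fold per subject). Per fold every
coefficient — seed, observation polynomials, noise variances, drift — is
refitted on the training trials only; the held-out trial(s) are predicted
and per-trial metrics recorded. Each fold stores a SHA-256 fingerprint of
its sorted training trial ids so leakage is checkable. The overall
cross-validated accuracy is the unweighted mean of held-out per-trial MAE.
The deployed coefficient set is the element-wise mean of the per-fold
coefficients (structure must match across folds; averaging is
order-invariant up to floating-point associativity, asserted to 1e-12 in
tests).

Before export every coefficient is reduced to 5 decimal places. The default
mode truncates toward zero (chosen so that rounding is idempotent and never
increases a coefficient's magnitude); half-even rounding is available as an
alternate. Variances (`q`, `r_j`, initial variance) are floored at 1e-5 so
the rounded parameter set remains valid. The full evaluation is re-run with
the rounded coefficients and the export fails if |ΔMAE| > 0.005 °C. The
coefficient table is a flat CSV (name, value, units, schema_version) written
with `repr` so it round-trips losslessly.

### 1.6 Model selection

A stateless multiple-linear-regression baseline (T_C on the minute features)
runs through the same cross-validation harness; candidates are ranked by
cross-validated MAE (ties: RMSE, then name) with a flag for the ≤ 0.3 °C
criterion. The deployed estimator is always the EKF — it is the model that
fits in device firmware — and the baseline remains in the ranking table as a
reference point.

## 2. The synthetic trial generator

### 2.1 Thermal model

A two-node (core/skin) heat-balance model integrated by explicit Euler at
1 s steps:

    c_core·dT_C/dt  = M·(1−η) − k(T_C)·(T_C − T_sk)
    c_skin·dT_sk/dt = k(T_C)·(T_C − T_sk) − h_env·(T_sk − t_a) − E_sw

with vasodilation `k(T_C) = k_cs·(1 + k_dilation·max(0, T_C − 37))` and
saturating sweating `E_sw = min(sweat_gain·max(0, T_C − 37.2), e_max)`,
multiplied by 0.25 under impermeable clothing. Metabolic heat is
piecewise-linear in activity intensity i with M(0) = 0:
`M = m_rest·i/i_rest` for i ≤ i_rest, else `m_rest + m_slope·(i − i_rest)`.

Key parameters (lumped whole-body values for a reference adult):

| parameter | default | units | why |
|---|---|---|---|
| c_core | 2.1e5 | J/°C | heat capacity of a ~60 kg core compartment |
| c_skin | 5.0e4 | J/°C | heat capacity of the skin shell |
| k_cs | 25 | W/°C | resting core→skin conductance |
| k_dilation | 1.5 | 1/°C | conductance gain per °C of T_C above 37; lets one parameter set hold rest near 37 °C *and* reach realistic exercise equilibria |
| h_env | 20 | W/°C | skin→air convective/radiative conductance |
| sweat_gain | 400 | W/°C | evaporative cooling per °C above threshold |
| sweat_threshold | 37.2 | °C | sweating onset |
| e_max | 600 | W | evaporative capacity cap |
| η (eta) | 0.15 | — | mechanical efficiency (work leaving the body) |
| m_rest, i_rest | 95, 0.35 | W, — | seated-rest metabolic rate and intensity |
| m_slope | 1100 | W/unit | metabolic rise above rest |

### 2.2 Sensors, subjects and protocols

Heart rate is `hr_rest + (hr_max − hr_rest)·i + k_drift·max(0, T_C − 37)`
with hr_max from the age formula `208 − 0.7·age` and Gaussian noise
(SD 2 beats/min) at 1 Hz. Skin temperature (SD 0.2 °C) and skin relative
humidity (from ambient RH plus skin wetness, SD 2 %) are sampled at 0.2 Hz.
Body surface area uses DuBois: `0.007184·mass^0.425·height^0.725`.

Reference T_C is sampled every 5–300 s (per-trial interval cycling through
60/15/300/120 s with rectal/gastrointestinal-pill device labels; the pill
can apply a first-order lag, default 0) with Gaussian noise SD 0.05 °C.
Starting T_C is drawn per trial around a sex-specific mean (36.9 °C male,
37.1 °C female, SD 0.12 °C).

Four study protocol templates span low- to high-intensity activity (segment
intensities 0.30–1.10, trial lengths 40–107 min) and cool-to-hot
environments (13–43.5 °C); the fourth template repeats sprints until T_C
exceeds a threshold, truncating the trial when T_C reaches 39.0 °C. A
known-coefficient mode (`SimConfig.obs_polynomials`) replaces the
physiological sensor channels with specified polynomials of the true T_C
plus noise, used by the parameter-recovery acceptance test.

Per-trial RNG seeds are drawn from the cohort seed (< 2³¹), so every cohort
is fully deterministic under one integer.

### 2.3 Generator limitations

The two-node model has no circadian rhythm, no explicit dehydration or
acclimatization state, a single lumped skin node (no regional gradients),
piecewise-linear metabolism, and a skin-humidity channel that is a crude
wetness proxy. It is designed to produce *plausible covariation* between
T_C and the sensor channels — enough to exercise every pipeline stage and
make parameter recovery meaningful — not to be a validated physiological
model. Accuracy numbers obtained on synthetic cohorts characterize the
pipeline on this generator's data and do not transfer to human data.

## 3. Aggregation and statistics conventions

- **Minute windows** are half-open, 0-based: minute m covers
  [60·m, 60·(m+1)) seconds; 60 samples at 1 Hz, 12 at 0.2 Hz. Aggregates:
  mean, min, max, median, SD (ddof = 1), count. Minutes with < 50 % of a
  stream's expected samples are flagged `incomplete`; trailing partial
  minutes are dropped.
- **Reference interpolation**: when the reference sampling interval exceeds
  60 s, the minute value is linear interpolation at the minute midpoint
  (flagged `interpolated`); at 60 s or faster it is the per-minute mean.
  No extrapolation outside the sampled span — those minutes are flagged
  `excluded` and never enter metrics.
- **Metrics** (errors are estimate − reference; positive bias =
  overestimation): MAE, RMSE, MAPE, Pearson r, bias, and "SEM" defined as
  the SD of the residuals (ddof = 1) with 95 % limits of agreement
  ±1.96·SD — this is the definition used in the wearable-validation
  literature, not the classical standard-error-of-measurement formula.
  Everything follows the trial-then-overall rule: compute per trial, then
  average unweighted across trials. Pearson r is NaN for constant series and
  averaged over the trials where it is defined (count reported).
- **Binned reports** slice by reference-T_C band (36.2–37.0, >37.0–38.0,
  >38.0–39.0, >39.0–40.2, upper endpoints inclusive), heart-rate zone
  (Lighter ≤ 57 %, Light ≤ 64 %, Moderate ≤ 75 %, Vigorous > 75 % of
  age-predicted maximum), ambient band (≤ 20, 20.1–30, > 30.1 °C), reference
  device, and sex. The Bland–Altman variant plots errors against the
  reference value rather than the pair mean (the reference is treated as
  truth). The error histogram rounds errors to one decimal (half-even) and
  reports the fraction of minutes within ±0.30 °C.
- **Feature screening** (used by the `featurize` stage): variance inflation
  factors computed with an intercept, iteratively removing the worst feature
  until all VIF ≤ threshold (default 5); backward elimination on OLS
  p-values (α = 0.05); univariate ranking by F = r²(n−2)/(1−r²).

## 4. Numerical choices

- Explicit Euler at 1 s: the thermal time constants (c/k ≈ 10³–10⁴ s) are
  vastly longer than the step, so stiffness is not a concern; non-finite
  states raise immediately.
- Floors: posterior variance 1e-12, fitted r 1e-12, fitted q 1e-8, rounded
  variances 1e-5 — all to keep the filter's divisions well-defined without
  materially affecting estimates.
- Rounding to 5 decimals uses `Decimal(repr(x))` so the operation is exact
  in decimal and idempotent.
- All randomness flows from a single integer seed via numpy Generators;
  derived seeds are drawn below 2³¹.

## 5. Limitations

- The estimator carries a single scalar state; it cannot represent
  channel-specific biases drifting over a trial.
- Observation models are global polynomials, not per-subject calibrations.
- The sex-only seed ignores age, acclimatization and time of day.
- All accuracy numbers in this repository are computed on synthetic data
  from the generator above; no claim is made about human-data performance.
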