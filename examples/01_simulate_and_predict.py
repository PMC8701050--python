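"""Simulate a small cohort, fit the estimator, and track one trial.

The generator produces raw 1 Hz / 0.2 Hz sensor streams plus sparsely
sampled reference core temperature; aggregation turns them into one-minute
feature tables; the extended Kalman filter then produces one core-
temperature estimate per minute, starting from a sex-seeded initial value.
"""

from tcore.ekf import EKFModelSpec, fit_ekf_params, predict_trial
from tcore.ingest import aggregate_cohort
from tcore.simulate import SimConfig, simulate_cohort

# a 6-subject synthetic cohort across the four study protocols
cohort = simulate_cohort(6, SimConfig(rng_seed=7))
frame = aggregate_cohort(cohort.trials)
print(f"{len(cohort.trials)} trials, {len(frame)} one-minute rows")

# fit every model component (seed regression, observation polynomials,
# process noise) on the whole cohort, then filter one trial
params = fit_ekf_params(frame, cohort.profiles, EKFModelSpec())
print(f"seed model: Tc0 = {params.seed.b0:.3f} + {params.seed.b_female:.3f} * female")
for ch in params.channels:
    terms = " + ".join(f"{c:.3g}*Tc^{i}" if i else f"{c:.3g}" for i, c in enumerate(ch.coeffs))
    print(f"  {ch.name}: z = {terms}  (r = {ch.r:.3g})")

trial = cohort.trials[0]
minutes = frame.loc[frame["trial_id"] == trial.trial_id]
preds = predict_trial(minutes, params, cohort.profiles[trial.subject_id])
print(f"\ntrial {trial.trial_id} ({trial.gt_device} reference):")
print(preds[["minute", "tc_hat", "tc_gt", "variance"]].head(10).to_string(index=False))
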