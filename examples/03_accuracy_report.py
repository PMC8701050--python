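"""Full accuracy report: overall, binned, Bland-Altman and error histogram.

Metrics follow the trial-then-overall convention (each trial's metrics are
computed on its own minutes, then averaged unweighted across trials), and
the binned tables slice accuracy by reference-temperature band, heart-rate
zone, ambient band, reference device, and sex.
"""

from tcore.ekf import EKFModelSpec
from tcore.ingest import aggregate_cohort
from tcore.simulate import SimConfig, simulate_cohort
from tcore.traincv import EKFCandidate, evaluate_final, run_cv, split_folds

cohort = simulate_cohort(8, SimConfig(rng_seed=19))
frame = aggregate_cohort(cohort.trials)
candidate = EKFCandidate(EKFModelSpec())
cv = run_cv(frame, cohort.profiles, candidate, split_folds(frame))

report = evaluate_final(candidate, cv.final_params, frame, cohort.profiles)
o = report["overall"]
print(f"overall: MAE {o.mae:.3f}  RMSE {o.rmse:.3f}  SEM {o.sem:.3f}  "
      f"r {o.pearson_r:.3f}  bias {o.bias:+.3f} degC  "
      f"({o.n_trials} trials, {o.n_minutes} min)")

print("\nby reference-temperature band:")
cols = ["bin", "n_minutes", "mae", "rmse", "bias"]
print(report["binned"]["gt_tc"][cols].to_string(index=False))

print("\nby heart-rate zone:")
print(report["binned"]["hr_zone"][cols].to_string(index=False))

ba = report["bland_altman"]
print(f"\nBland-Altman: bias {ba.bias:+.3f} degC, "
      f"95% LOA [{ba.loa_lower:+.3f}, {ba.loa_upper:+.3f}]")
print(f"fraction of minutes within +/-0.30 degC: {report['frac_within_0p30']:.2f}")

print("\nerror distribution (degC bucket: minutes):")
for bucket, count in report["error_histogram"].items():
    print(f"  {bucket:+.1f}: {int(count)}")
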