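"""Correct one subject's FA profile to the test-set mean age.

The trained network is frozen; gradient descent runs on the *input*
instead of the weights. Each iteration takes one transient gradient step
on the hidden matrix (W -> W') and converts it into an input update
x <- x W' W^-1, under three rules: FA may only move in the direction
consistent with the age shift, and SCP/MCP never change. The per-subject
target y_pred + (target_age - chron_age) preserves the brain-age gap.
"""

import tractage as ta

cohort = ta.generate_cohort(ta.GeneratorConfig(n_subjects=217, seed=7))
pipe = ta.train_pipeline(cohort, seed=7, fast=True)

target = pipe.test_mean_age()
subject = pipe.split.test.iloc[0]
config = ta.CorrectionConfig(global_target_age=target)
res = ta.ann_age_correct(pipe.ann, pipe.scaler, subject, config)

print(f"subject {subject.subject_id}: chronological age {subject.age:.1f} y")
print(f"global target age {target:.1f} y")
print(f"predicted brain age {res.y_initial:.1f} y -> target {res.y_target:.1f} y")
print(f"converged in {res.iterations} iterations, "
      f"final error {res.final_error * 12:.2f} months")
print(f"prediction on corrected FA: {res.y_final:.1f} y")

changed = (res.corrected_fa - subject[list(ta.TRACT_NAMES)]).astype(float)
print("\nlargest FA changes (frozen SCP/MCP are exactly zero):")
print(changed.abs().sort_values(ascending=False).head(5).round(4).to_string())
print(f"SCP change: {changed['SCP']}, MCP change: {changed['MCP']}")
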