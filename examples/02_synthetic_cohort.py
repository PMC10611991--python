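"""Generate a synthetic cohort and compare observation with hidden truth.

The generator draws a latent true completion status per participant and
then passes it through the observation channels the analysis worries
about: imperfect self-report (sensitivity/specificity) and follow-up
attendance that depends on the true outcome.  Truth is returned
separately, so we can see the bias the channels induce.
"""

from misoqba import default_paper_config, effectiveness_counts, generate

cfg = default_paper_config(seed=11)
records, truth = generate(cfg)

crude = effectiveness_counts(records, "last_recorded")["complete_no_procedure"]
n = len(records)
lost = sum(1 for r in records if not r.fu2_attended)

print(f"n = {n}, seed = {cfg.seed}")
print(f"true completion (hidden):       {truth['true_complete'].mean():.4f}")
print(f"observed crude effectiveness:   {crude / n:.4f} ({crude}/{n})")
print(f"missed the 3-week follow-up:    {lost}")
print()
print("The gap between truth and observation comes from self-report")
print(f"sensitivity {cfg.selfreport_sensitivity} / specificity "
      f"{cfg.selfreport_specificity} and attendance probabilities "
      f"{cfg.fu2_attendance_prob} that depend on the true outcome.")
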