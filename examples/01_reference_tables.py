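"""Effectiveness endpoints on the margin-matched reference cohort.

Builds the deterministic 637-record reference cohort, classifies the
primary outcome (abortion completion without procedural intervention) at
each follow-up, and prints the proportions with 95% Wilson score
intervals, overall and by regimen.
"""

from misoqba import (
    derive_frame, effectiveness_counts, proportion_ci, reference_cohort,
    tabulate,
)

cohort = reference_cohort()
frame = derive_frame(cohort)

print(f"cohort: {len(cohort)} participants\n")
for tp, label in (("fu1", "1-week follow-up"),
                  ("fu2", "3-week follow-up"),
                  ("last_recorded", "last recorded follow-up")):
    counts = effectiveness_counts(cohort, tp)
    denom = sum(counts.values())
    res = proportion_ci(counts["complete_no_procedure"], denom)
    print(f"effective at {label:24s} {res}")

print("\nby regimen at last recorded follow-up:")
tab = tabulate(frame, "eff_last", strata="regimen")
print(tab.to_text())

print("\nEach line is the number completing without manual vacuum")
print("aspiration or D&C over the follow-up denominator; the interval is")
print("a 95% Wilson score interval for that proportion.")
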