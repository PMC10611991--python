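# Methods

## Study setting and endpoints

The package analyses prospective cohorts of people self-managing a
medication abortion with misoprostol alone, interviewed by phone about
one week and about three weeks after the first dose. All outcomes are
self-reported; there is no clinical gold standard.

**Effectiveness** is abortion completion *without* procedural
intervention (manual vacuum aspiration or dilation & curettage/
evacuation). Classification precedence per participant and time point:

1. procedural intervention by the time point **and** a completion
   self-report → `complete_with_procedure`;
2. completion self-report, no intervention → `complete_no_procedure`;
3. self-report "not complete or not sure" → `not_complete_or_unsure`,
   regardless of intervention — this joint cell is never printed in the
   source tables, so the classifier follows the self-report and logs the
   conflict rather than guessing;
4. otherwise `missing`.

The two site-specific question wordings ("is your abortion complete?" /
"are you still pregnant?") are harmonized to one binary field at ingest.
"Not complete" and "not sure" form one class. A participant whose
completion judgement rests only on symptom resolution is classified like
one with a negative test: the tables condition on the answer, not its
basis.

**Last recorded follow-up** uses the 3-week classification when that
interview was attended, else the 1-week classification (carry-forward).
Denominators: 1-week attendees at the first follow-up, 3-week attendees
at the second, everyone with at least one follow-up at last-recorded.

**Safety composites** are ORs over checklists measured across both
follow-ups: four warning signs (bleeding soaking >2 pads/h for >2 h,
pain unrelieved by analgesics, fever >38 °C for >24 h, foul discharge)
and three adverse-event markers (IV fluids, transfusion, overnight
hospital stay). A composite is missing only when every component is
missing; such participants stay in denominators under the descriptive
policy.

## Descriptive statistics

Binomial CIs default to the **Wilson score interval without continuity
correction**, which reproduces both published bounds of the two primary
effectiveness cells at one-decimal rounding ((625, 637) → 96.7–98.9 and
(605, 635) → 93.3–96.7). Some published small-count cells (e.g. 6/637 →
0.4–2.1) do not match Wilson at one decimal; the method is therefore
configurable (`wilson` | `clopper_pearson`) and the golden tests assert
only the verified cells. The exact rounding rule applied to borderline
published bounds is unknowable from the printed tables; affected cells
are excluded from golden checks.

Percentages round **half away from zero at one decimal**, matching the
printed tables (Python's default bankers rounding would differ at .x5).

Missing-data policy: `missing_in_denominator` for descriptive tables
(missing appears as a row and counts toward column totals);
`missing_excluded` for inferential comparisons (missing categories are
dropped before testing). `tabulate` is invariant to record order, and an
empty cohort yields an empty table rather than a division by zero.

The expulsion-time summary counts observed expulsions within a cutoff
over the **whole cohort**: never-noticed products of conception and
missing times count as not-within.

## Contingency-table inference

Pearson chi-square of independence without Yates correction (the
correction is available as a flag), df = (r−1)(c−1), upper-tail p.
The Fisher exact two-sided p uses **probability ordering**: the sum of
probabilities of all tables with the observed margins whose point
probability does not exceed the observed table's (conventions differ;
this is the dominant one and the one an enumeration oracle defines
unambiguously). For r×c tables an exact p is computed by recursive
enumeration of margin-fixed tables when the total count is at most
`mc_threshold` (default 10 000 — fine for the care-seeking-sized tables
this package targets; genuinely large sparse r×c tables should lower
it), otherwise a Monte Carlo p from margin-fixed random tables
(add-one estimator, seed recorded in the result). Significance reporting
uses the conventional two-sided 0.05.

A note on asymptotics: with all expected counts around 20 the
uncorrected chi-square and the exact probability-ordering p can still
differ by ~0.03; the agreement tightens below 0.02 only once expected
counts reach the order of 100. The test suite checks this convergence
rather than a fixed gap at small counts.

## Quantitative bias analysis

Summary-level (count-based) probabilistic bias analysis, chosen over
record-level reclassification because only marginal counts enter the
reported estimate and the summary level admits exact closed-form oracles
for testing. Per iteration, with draws (Se, Sp, a_c, a_i):

1. **Misclassification correction.** p = (p_obs − (1−Sp)) / (Se+Sp−1),
   where p_obs is the crude proportion among followed participants.
   Requires Se+Sp > 1. A result outside [0, 1] marks the draw as
   logically incompatible with the data.
2. **Selection adjustment.** Corrected complete/incomplete counts among
   the followed are weighted by 1/a_c and 1/a_i — inverse probability of
   attending the final follow-up given the true outcome. Equal
   attendance cancels exactly.
3. **Random error.** The final count is drawn from
   Binomial(n_total, adjusted p).

This order (misclassification → selection → random error) is the
conventional sequence for summary-level probabilistic bias analysis.
Impossible draws are **discarded and tallied** by default (truncation to
the boundary is available); discarding keeps the interval interpretable
as a distribution over parameter values compatible with the data. The
point estimate is the median of kept draws (mean available); the
simulation interval is the equal-tailed 2.5th–97.5th percentile pair.
Everything is vectorized over iterations and reproducible from a single
seed; 50 000 iterations run in well under a second on one CPU.

**Priors.** The bias-parameter distributions are configuration, not
estimates. Supported families: point mass, uniform, beta, trapezoidal,
all restricted to (0, 1]. The defaults pin sensitivity at
trapezoidal(0.99, 0.995, 1, 1): with a crude proportion near 0.99, any
Se draw below p_obs is *logically impossible* (the corrected proportion
exceeds 1 even if everyone is truly complete), so an admissible
sensitivity prior must sit essentially at 1 — consistent with validation
work showing self-assessment of abortion completion is highly sensitive.
Specificity gets a deliberately wide uniform(0.75, 1); attendance priors
are uniform(0.9, 1) given a complete abortion and uniform(0.5, 0.9)
otherwise. These defaults are illustrative and unanchored to any
specific validation study; analyses should substitute setting-specific
priors through `BiasParameters`.

## Synthetic-cohort generator

`synth.generate` emulates the data-generating process the analysis
assumes: latent true completion per participant with probability set by
pregnancy-duration bin × regimen; self-report drawn from truth through
Se/Sp channels independently at each follow-up; 3-week attendance drawn
Bernoulli conditional on the true outcome (the differential-loss
channel); procedural interventions via small per-truth probabilities;
warning signs conditional on truth; and physical-experience variables
(expulsion times, bleeding/cramping durations, side effects) drawn from
the published bin frequencies, uniform within bins since only binned
data are printed. Truth is returned separately and never written to the
observed file, giving misclassification-recovery tests the gold standard
the real study lacks.

Each field draws from its own named substream (fixed spawn-key
registry), so output is bit-identical for a (config, seed) pair and
adding a field never perturbs existing draws.

The default configuration matches the published margins: n = 637, site
mix 591/45/1, duration mix 317/205/92/23, regimen mix 532/105, true
completion at the published stratum rates, attendance tuned so ~45 of
637 miss the 3-week interview (0.933 given complete vs 0.70 given
incomplete), Se = 0.99 and Sp = 0.95 as mild default observation noise.
Warning-sign probabilities conditional on a truly incomplete abortion
are not identifiable from published margins and are free, flagged
defaults chosen to reproduce the observed ~8% composite prevalence.

What the generator does **not** emulate: site × regimen × duration
dependence (fields are drawn independently, so joint cells are off the
published joints even though margins match), gestational-age-dependent
symptom biology beyond the printed conditional frequencies, covariate-
dependent attrition richer than the outcome-conditional Bernoulli, and
within-person correlation between the two follow-up reports. Passing
tests therefore demonstrate correctness of the analysis machinery under
the stated model, not fidelity of any richer structure in real data.

## Reference cohort

`reference.reference_cohort()` builds 637 records by deterministic
constrained assignment — not sampling — so that published margins are
hit exactly: the follow-up structure (635/592/45), all effectiveness
classes at all three time points overall, by duration stratum and by
regimen, warning-sign components and composite (including the one
participant with missing safety data kept in denominators), adverse
events, the care-seeking cross-tabulations, expulsion-time bins,
bleeding/cramping distributions and side-effect counts. Joint cells the
study never printed (which duration stratum each care seeker occupies,
which specific rows carry two warning signs, etc.) are fixed by
arbitrary-but-deterministic rules; only the margins carry meaning. The
rows are synthetic reconstructions, not real participants.

## Problem sizes and numerical choices

- QBA runs use 50 000 iterations (the default), where Monte Carlo error
  on the median is well below 0.01.
- The parameter-recovery check generates a cohort of n = 20 000: the
  misclassification correction divides cohort sampling noise by
  (Se+Sp−1), so at n = 637 the corrected proportion has a standard error
  of roughly 0.016 under Se = 0.97, Sp = 0.85 and a ±0.01 recovery band
  is only meaningful at larger n.
- Generator calibration is checked as mean per-category counts over
  repeated seeds against a 4-standard-error band for the replicate mean.
- Wilson bounds are verified against a score-equation root-finder
  (Brent's method, xtol 1e-14) to 1e-10; Fisher 2×2 against full
  hypergeometric enumeration; chi-square against direct Σ(O−E)²/E.
- Probability vectors must sum to 1 within 1e-9; config validation
  names the offending field.
- Floating-point ties in "at least as extreme" comparisons use a 1e-9
  relative epsilon.

## Limitations

The package corrects a single binary endpoint at the summary level; it
does not model time-to-event structure in expulsion or bleeding, effect
sizes for group comparisons (no odds-ratio CIs), covariate-driven
attrition, or correlated misclassification across follow-ups. The
default bias priors are illustrative; conclusions from `run_qba` are
conditional on the priors supplied.
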