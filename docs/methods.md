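# Methods

`riskscreen` implements a stepped violence-risk screening strategy for
patients discharged from hospital with schizophrenia: a cheap five-item rule
first screens out subjects at very low risk of a subsequent violent
conviction, so that resource-intensive clinical risk assessment can be
concentrated on the remainder. This note documents the statistical model
behind each stage, the defaults and why they were chosen, what the synthetic
cohort does and does not emulate, and the numerical conventions.

## The screening tool

The tool is a unit-scored model over five routinely available items: male
sex, any previous criminal conviction, young age at assessment
(age < 32 years), comorbid alcohol abuse, and comorbid drug abuse. Each item
present scores +1; a subject screens in (proceeds to full assessment) when
the total score is at least the cut-off, otherwise screens out. A clinical
override can force a screen-in — never a screen-out — so clinician judgement
can only make the rule more conservative.

Because the tool exists to *rule out*, the operative statistic is the
negative predictive value (NPV): the fraction of screened-out subjects who
are not subsequently convicted. PPV, the diagnostic odds ratio
(DOR = TP·TN / FP·FN) and the trapezoidal AUC complete the reporting set;
DOR and AUC are base-rate independent, NPV and PPV are not.

## Cohort simulation

No register data can ship with the package, so every downstream stage is
exercised on a simulated cohort designed to match the published marginal
structure of the calibration sample:

- **Covariates.** Independent Bernoulli draws at the calibration-sample
  prevalences (male 0.636, prior conviction 0.407, alcohol 0.156, drug
  0.167, plus five secondary familial/educational covariates). Independence
  is a deliberate simplification — real comorbidity and criminal history are
  correlated — so simulated joint distributions of items, and any statistic
  sensitive to them, should not be read as estimates of the real ones.
- **Age.** A two-parameter log-normal truncated to [15, 54] years. The
  printed targets (median 26, IQR 22–33) are slightly right-skewed relative
  to any log-normal, so the two parameters are fitted by least squares to
  the three log-quantiles; each realised quantile lands within about one
  year of its target.
- **Event times.** Exponential with hazard
  `h = h0 · 3.3^male · 3.3^prior · 1.9^young · 2.9^alcohol · 3.5^drug`,
  where `young = 1{age < 32}`. A constant baseline hazard is the simplest
  law compatible with proportional hazards; the accuracy pipeline only uses
  event-by-horizon indicators, so the choice of baseline shape is
  immaterial there, and it keeps parameter recovery analytic. A hazard
  ratio of exactly 0 is accepted as a sentinel meaning "factor disabled"
  (multiplier 1); negative values are rejected.
- **Censoring.** The minimum of an independent exponential death/emigration
  clock (default 0.010 / person-year) and an administrative cut drawn
  uniformly over (0, 32] years, approximating staggered cohort entry over a
  32-year observation window with a fixed closing date.
- **Baseline hazard default.** `8.1e-4` events per person-year for a
  zero-covariate subject, found once by bisection on pilot simulations so
  that the default configuration yields a lifetime violent-conviction
  fraction of ≈ 12.9%, and then frozen.

What passing tests on this cohort demonstrate: that the estimation machinery
(Cox fitting, age cut-point search, cut-off selection, the accuracy and
comparison statistics) recovers planted truth under the study's marginal
conditions. What they do not demonstrate: performance of the tool on real
register data, where covariates are correlated, hazards are non-constant in
time, and censoring is not independent of risk.

## Printed-count fixtures

The calibration sample's per-score outcome counts at the 1-, 2- and 5-year
horizons are embedded as cumulative true-positive / false-positive columns
and differenced into per-score offender / non-offender counts
(`make_table2_fixture`). `fixture_cohort` materialises them as a
subject-level cohort — score *s* realised by switching on the first *s*
coding-sheet items — so the scoring, cut-off-selection and accuracy code
paths are exercised end-to-end, not just the arithmetic. Fixture mode is a
first-class execution path of `run_study`, which is how the published
calibration tables are reproduced exactly without any simulation.

## Estimation details

**Cox fitting** (`fit_cox`) is delegated to `statsmodels.PHReg`. Efron tie
handling is the default (more accurate than Breslow when a simulator or a
coarse time grid produces ties); Breslow is available and the two agree
exactly on tie-free data. Monotone partial likelihoods (perfect separation)
are diagnosed from implausibly large standardized coefficients or exploded
standard errors and raised as `ConvergenceError` rather than returned
silently. Item selection keeps covariates with two-sided Wald p < 0.05 in
the joint model.

**Age cut-point** (`select_age_cutoff`) reduces chi-square-based recursive
partitioning to the single binary split that one ordinal predictor needs:
candidate thresholds are midpoints of adjacent distinct ages; at each, the
observed event counts below/above are compared to person-time-expected
counts under a common rate (the "adjusted by time at risk" element), and the
Pearson chi-square is maximised. The best split's p-value carries a
Bonferroni penalty for the number of candidates, and the result records
whether any split is supported at α = 0.05. Ties break toward the smaller
threshold; candidates leaving < 1% of total exposure on one side are
excluded as degenerate. Whether the original procedure used raw event
counts or a rate-adjusted statistic is not documented anywhere; the
exposure-adjusted form is adopted because follow-up time varies strongly
with age at assessment.

**Score cut-off** (`select_score_cutoff`). "Maximise sensitivity while
balancing specificity" is operationalised as: the largest cut-off whose
sensitivity is still ≥ a floor (default 0.85), falling back to 0 if none.
This rule reproduces the published choice (cut-off 2) at all three horizons,
whereas e.g. the Youden index would pick 3 at the 2- and 5-year horizons.
The floor is configurable. In simulation mode the cut-off is chosen per
horizon and the minimum is frozen — the most sensitivity-protective
tie-break; at the published operating points all horizons agree anyway.

**At-risk exclusion.** At horizon *h*, subjects convicted within *h* years
are positives; subjects followed at least *h* years without conviction are
negatives; event-free subjects censored before *h* are excluded, so each
horizon's 2×2 table is well defined. The young-age predicate is strict
(`age < threshold`); the source material never says strict-vs-inclusive, so
it is configurable via the stored threshold.

**Confidence intervals.** Wilson score for all proportions; log-normal
(`exp(ln DOR ± 1.96·√(1/a+1/b+1/c+1/d))`) for the DOR; Hanley–McNeil
standard error with a Wald interval for the AUC
(Q1 = A/(2−A), Q2 = 2A²/(1+A)). The original report's interval methods are
unstated and its own AUC intervals are internally inconsistent, so point
estimates — not intervals — are the reproduction surface.

**Zero cells.** A zero FP·FN or TP·TN product leaves the DOR undefined;
`accuracy_summary` raises unless the Haldane–Anscombe +0.5 correction is
enabled. The pipeline enables it (it only engages when a cell is actually
zero, so fixture-mode numbers are untouched); the same policy applies to
the Breslow–Day strata, whose Mantel–Haenszel common odds ratio is likewise
undefined with empty cells. Small replication samples at the 1-year horizon
regularly have zero false negatives, so this is the difference between a
corrected estimate and an aborted study.

**Base-rate projection.** Exact Bayes:
`PPV = se·π / (se·π + (1−sp)(1−π))`, `NPV = sp(1−π) / (sp(1−π) + (1−se)π)`,
with the exact limits PPV = 0, NPV = 1 at π = 0. The published base-rate
table's "0%" column shows 0.01/0.99, i.e. the observed sub-1% base rate
rather than the limit; the projection implements the exact formula and the
discrepancy is a display matter (below), not imitated in the math.

**Displayed proportions.** Printed screening tables never display an
interior proportion as 0.00 or 1.00 — a rule with six false negatives must
not be printed as perfect. Table rendering therefore clips two-decimal
half-up-rounded proportions to [0.01, 0.99] unless the value is exactly 0
or 1 (`display_proportion`). This single convention reconciles every
printed NPV/PPV cell (e.g. 1-year NPV 2353/2359 = 0.9975 displays as 0.99)
while raw values remain available everywhere in the API. All printed-table
comparisons are at two decimals, half-up.

**Shrinkage battery** (`compare`). Calibration vs each replication sample,
per horizon: Pearson chi-square (df 1, no continuity correction) on the NPV
complements (convicted among screened-out); the Breslow–Day chi-square for
homogeneity of the screening tables' odds ratios (no Tarone correction by
default, matching the cited test; Tarone available behind a flag); and the
independent-samples Hanley–McNeil z for AUC differences (calibration and
replicates share no subjects, so the correlated-ROC variant is
unnecessary). All three hold their nominal size within [0.03, 0.07] in
seeded null simulations of 1,000 replicates.

**Incremental validity.** A candidate extra item (e.g. low education) is
judged to improve the tool only if the extended score's AUC is higher with
Hanley–McNeil p < 0.05 at at least one horizon. Under the default
simulation, where secondary covariates carry no hazard, they are dropped.

## Splitting and determinism

`split_cohort` assigns half the cohort (floor) to calibration and splits the
remainder into equal replicates, any indivisible leftover going to
calibration with a log line; 13,806 subjects yield the study's 6,903 +
3 × 2,301 design. One seed drives a `numpy` Generator per stage;
`run_study` with a fixed config and seed produces byte-identical JSON
reports (timestamps excluded). Replicates are always evaluated with the
calibration-frozen tool — threshold, items and cut-off are never
re-estimated, which is what makes the comparisons a shrinkage test.

## Problem sizes used by the test suite

Parameter-recovery checks use what each property needs and no more:
n = 50,000 for hazard-ratio recovery (fit CIs ≈ ±6% there), n = 20,000 for
the age cut-point (±2-year recovery band), n = 1,000 seeded replicates for
the size of each comparison test, and tiny hand-checkable instances (4–8
subjects) for the exact-oracle identities. The full simulated study runs at
the design size of 13,806.

## Known limitations

- Covariate independence in the simulator (no copula over items).
- Constant baseline hazard and age-invariant censoring; real discharge
  cohorts show neither.
- The Hanley–McNeil AUC variance is an approximation for discrete
  six-point scores; it is used for intervals and z tests, never for point
  estimates.
- The incremental-validity comparison treats base and extended AUCs from
  the same sample as independent, which is conservative in the direction of
  not adding items.
- `fit_cox` offers no time-varying covariates, stratified baselines or
  frailty terms; they are out of scope for a fixed-at-discharge screener.
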