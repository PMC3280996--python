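# riskscreen

Stepped violence-risk screening for patients discharged from hospital with
schizophrenia: build and validate a five-item rule that screens out people
at very low risk of a post-discharge violent conviction, so that detailed
clinical risk assessment can be reserved for everyone else.

## The problem and the model

Treatment guidelines ask for violence risk to be assessed in everyone with
schizophrenia, but structured assessments take hours per patient while the
conviction base rate is low (≈ 13% over decades of follow-up, ≈ 1% within a
year of discharge). A *rule-out-first* strategy inverts the usual logic:
a cheap screen with very high sensitivity removes the very-low-risk group,
and only screen-positives proceed to full assessment.

The screen is a unit-scored model: +1 for each of **male sex**, **previous
criminal conviction**, **age at assessment < 32 years**, **comorbid alcohol
abuse**, **comorbid drug abuse**; screen in iff score ≥ 2, with a clinical
override that can force a screen-in (never a screen-out). The age threshold
comes from an exposure-adjusted chi-square split search, the items from a
joint Cox proportional-hazards fit (retain covariates with Wald p < 0.05),
and the cut-off from a sensitivity-floor rule (largest cut-off with
sensitivity ≥ 0.85).

Performance is reported per follow-up horizon h ∈ {1, 2, 5} years on the
at-risk subset (subjects censored event-free before h are excluded), as

- NPV = TN/(TN+FN) and PPV = TP/(TP+FP) (base-rate dependent),
- diagnostic odds ratio DOR = TP·TN/(FP·FN),
- trapezoidal AUC over the empirical ROC, with Hanley–McNeil SE,

plus a Bayes projection of PPV/NPV onto hypothetical base rates π:
PPV(π) = se·π / (se·π + (1−sp)(1−π)). A shrinkage battery (two-proportion
χ², Breslow–Day homogeneity of odds ratios, Hanley–McNeil AUC z) compares
the calibration sample against independent replication samples evaluated
with the frozen tool.

Because the underlying national registers are not public, the package ships
two complementary data paths: a register-style cohort **simulator**
(covariate prevalences, planted hazard ratios, log-normal ages, exponential
conviction/censoring clocks, staggered administrative entry) and
**printed-count fixtures** that reconstruct the calibration sample's
per-score outcome counts exactly. See `docs/methods.md` for the full model
and its assumptions.

## Worked example

Score a single subject from the shell — a 24-year-old man with no prior
conviction and no comorbid substance abuse:

```
$ riskscreen score --male --age 24
score 2/5 -> screen_in
$ riskscreen score --age 40 --override
score 0/5 -> screen_in (clinical override applied)
```

Young men always reach the cut-off on sex and age alone, which is why the
screen discriminates best in women and older men; the second call shows the
override forcing a screen-in for a zero-score subject.

The analysis scripts run the full study. `analysis/04_fixture_tables.py`
evaluates the tool on the fixture-reconstructed calibration sample:

```
$ python analysis/04_fixture_tables.py
selected score cut-off: 2
horizon 1y (n = 6645): NPV 0.99, PPV 0.01, DOR 3.79, AUC 0.67, screened out 2359
horizon 2y (n = 6407): NPV 0.99, PPV 0.02, DOR 4.58, AUC 0.69, screened out 2255
horizon 5y (n = 5666): NPV 0.99, PPV 0.05, DOR 5.17, AUC 0.69, screened out 1983
1-year operating point projected to a 10% base rate: PPV 0.13, NPV 0.96
```

Reading the 1-year line: of 6,645 subjects at risk for a full year, 2,359
scored below 2 and were screened out; 2,353 of them (NPV 0.99) had no
violent conviction within the year. The low PPV is expected at a ≈ 0.7%
one-year base rate and is the point of the design — screen-positives are
not "high risk", they simply proceed to ordinary assessment. The projection
shows how the same operating point (se 0.87, sp 0.36) would behave in a
population with a 10% base rate.

The other drivers cover the simulated path: `01_simulate_cohort.py`
(13,806 subjects; lifetime conviction fraction ≈ 0.129),
`02_fit_hazards.py` (recovers the planted hazard ratios 3.3 / 3.3 / 1.9 /
2.9 / 3.5 on the calibration half), `03_build_tool.py` (age threshold
≈ 32, five items retained, cut-off 2) and `05_cross_validate.py` (frozen
tool on three replication samples of 2,301 plus the shrinkage battery).
Outputs land under `results/`; the cohort CSV goes to `scratch/`.

## Layout

```
src/riskscreen/     library: synth_cohort, survival, toolbuild, accuracy,
                    compare, pipeline, cli
analysis/           numbered study drivers (simulate -> fit -> build ->
                    fixture tables -> cross-validate)
tests/              pytest suite (unit, property and reproduction tests)
scripts/            acceptance script
docs/methods.md     model, defaults, numerical conventions, limitations
```
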