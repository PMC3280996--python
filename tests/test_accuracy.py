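"""At-risk exclusion, contingency tables, accuracy statistics, projections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import mannwhitneyu

from riskscreen import (
    ContingencyTable,
    RocCurve,
    accuracy_summary,
    at_risk_subset,
    auc_trapezoid,
    confusion_by_score,
    project_predictive_values,
    roc_from_confusion,
)
from riskscreen.accuracy import display_proportion, outcome_at_horizon, round_half_up, table_row
from riskscreen.errors import DegenerateTableError, UndefinedValueError
from conftest import fixture_confusion


# ---------------------------------------------------------------------------
# At-risk exclusion rule

def test_early_offender_kept_as_positive(small_cohort):
    sub = at_risk_subset(small_cohort, 1.0)
    assert "a" in sub["id"].values  # event at 0.4y
    assert outcome_at_horizon(sub, 1.0)[list(sub["id"]).index("a")] == 1


def test_event_free_early_censoring_excluded():
    df = pd.DataFrame(
        {
            "id": ["x"],
            "followup_years": [0.8],
            "event": [0],
            "censor_cause": ["death_or_emigration"],
        }
    )
    assert len(at_risk_subset(df, 1.0)) == 0


def test_fully_followed_negative_kept():
    df = pd.DataFrame(
        {"id": ["y"], "followup_years": [1.0], "event": [0], "censor_cause": ["end_of_study"]}
    )
    assert len(at_risk_subset(df, 1.0)) == 1


def test_at_risk_requires_positive_horizon(small_cohort):
    with pytest.raises(ValueError):
        at_risk_subset(small_cohort, 0.0)


# ---------------------------------------------------------------------------
# Confusion tables

def test_one_year_cutoff_two_row(confusion_1y):
    ct = table_row(confusion_1y, 2)
    assert (ct.tp, ct.tn, ct.fp, ct.fn) == (41, 2353, 4245, 6)


def test_two_year_cutoff_five_row():
    ct = table_row(fixture_confusion(2), 5)
    assert (ct.tp, ct.tn, ct.fp, ct.fn) == (9, 6104, 210, 84)


def test_cutoff_zero_row_everyone_positive(rng):
    scores = rng.integers(0, 6, 200)
    outcomes = rng.integers(0, 2, 200)
    conf = confusion_by_score(scores, outcomes)
    row = conf.loc[conf["cutoff"] == 0].iloc[0]
    assert row["fn"] == 0 and row["tn"] == 0
    assert row["sensitivity"] == 1.0 and row["specificity"] == 0.0


def test_margins_constant_across_cutoffs(rng):
    scores = rng.integers(0, 6, 500)
    outcomes = rng.integers(0, 2, 500)
    conf = confusion_by_score(scores, outcomes)
    assert (conf["tp"] + conf["fn"]).nunique() == 1
    assert (conf["fp"] + conf["tn"]).nunique() == 1


# ---------------------------------------------------------------------------
# Accuracy statistics

def test_one_year_calibration_statistics():
    rep = accuracy_summary(ContingencyTable(tp=41, fp=4245, tn=2353, fn=6))
    assert display_proportion(rep.npv) == 0.99
    assert display_proportion(rep.ppv) == 0.01
    assert round_half_up(rep.dor) == 3.79
    assert rep.screened_out == 2359


def test_five_year_calibration_statistics():
    rep = accuracy_summary(ContingencyTable(tp=202, fp=3481, tn=1961, fn=22))
    assert round_half_up(rep.dor) == 5.17
    assert display_proportion(rep.npv) == 0.99


def test_ci_bounds_bracket_estimates():
    rep = accuracy_summary(ContingencyTable(tp=41, fp=4245, tn=2353, fn=6))
    for name, value in [
        ("sensitivity", rep.sensitivity),
        ("specificity", rep.specificity),
        ("npv", rep.npv),
        ("ppv", rep.ppv),
        ("dor", rep.dor),
    ]:
        lo, hi = rep.ci[name]
        assert lo <= value <= hi, name


def test_degenerate_table_dor_undefined_without_correction():
    ct = ContingencyTable(tp=1, fp=0, tn=1, fn=0)
    assert ct.sensitivity == 1.0 and ct.specificity == 1.0
    with pytest.raises(DegenerateTableError):
        accuracy_summary(ct)
    rep = accuracy_summary(ct, continuity=True)
    assert rep.dor == pytest.approx((1.5 * 1.5) / (0.5 * 0.5))


def test_point_estimates_scale_invariant():
    a = accuracy_summary(ContingencyTable(tp=41, fp=4245, tn=2353, fn=6))
    b = accuracy_summary(ContingencyTable(tp=410, fp=42450, tn=23530, fn=60))
    for attr in ("sensitivity", "specificity", "npv", "ppv", "dor"):
        assert getattr(a, attr) == pytest.approx(getattr(b, attr), rel=1e-12)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(tp=-1, fp=0, tn=0, fn=0)


# ---------------------------------------------------------------------------
# ROC / AUC

def test_roc_is_monotone_and_anchored(confusion_1y):
    roc = roc_from_confusion(confusion_1y)
    assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
    assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
    assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)


def test_auc_needs_two_points():
    with pytest.raises(ValueError):
        auc_trapezoid(RocCurve([0.5], [0.5]), 10, 10)


def test_nondecreasing_roc_enforced():
    with pytest.raises(ValueError):
        RocCurve([0.0, 0.5, 0.4], [0.0, 0.5, 1.0])


def test_auc_near_half_for_uninformative_scores(rng):
    n = 4000
    scores = rng.integers(0, 6, n)
    outcomes = rng.integers(0, 2, n)
    conf = confusion_by_score(scores, outcomes)
    auc, se, _ = auc_trapezoid(
        roc_from_confusion(conf), int(outcomes.sum()), int(n - outcomes.sum())
    )
    assert abs(auc - 0.5) < 3 * se


def test_hanley_mcneil_se_formula():
    auc, se, ci = auc_trapezoid(roc_from_confusion(fixture_confusion(1)), 47, 6598)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + 46 * (q1 - auc**2) + 6597 * (q2 - auc**2)) / (47 * 6598)
    assert se == pytest.approx(np.sqrt(var), rel=1e-12)
    assert ci[0] < auc < ci[1]


# ---------------------------------------------------------------------------
# Base-rate projection

def test_projection_matches_printed_ten_percent_column():
    ppv, npv = project_predictive_values(41 / 47, 2353 / 6598, 0.10)
    assert round_half_up(ppv) == 0.13
    assert round_half_up(npv) == 0.96


def test_projection_zero_prevalence_exact():
    ppv, npv = project_predictive_values(0.87, 0.36, 0.0)
    assert ppv == 0.0 and npv == 1.0


def test_projection_rejects_out_of_range():
    with pytest.raises(ValueError):
        project_predictive_values(1.2, 0.5, 0.1)


def test_projection_undefined_denominator():
    with pytest.raises(UndefinedValueError):
        project_predictive_values(0.0, 1.0, 0.5)  # nobody tests positive


@given(
    se=st.floats(0.05, 0.99),
    sp=st.floats(0.05, 0.99),
)
def test_ppv_nondecreasing_npv_nonincreasing_in_base_rate(se, sp):
    grid = np.linspace(0.0, 0.5, 26)
    vals = [project_predictive_values(se, sp, pi) for pi in grid]
    ppvs = [v[0] for v in vals]
    npvs = [v[1] for v in vals]
    assert all(a <= b + 1e-12 for a, b in zip(ppvs, ppvs[1:]))
    assert all(a >= b - 1e-12 for a, b in zip(npvs, npvs[1:]))


def test_round_half_up_ties():
    assert round_half_up(0.125) == 0.13
    assert round_half_up(0.865) == 0.87
    assert round_half_up(-0.125) == -0.13


def test_auc_equals_mann_whitney_on_random_instances(rng):
    """Trapezoid over the empirical ROC equals the probability-of-correct-
    ranking estimator with half credit for ties, to 1e-12."""
    for _ in range(25):
        n = int(rng.integers(20, 80))
        scores = rng.integers(0, 6, n)
        outcomes = rng.integers(0, 2, n)
        if outcomes.sum() in (0, n):
            continue
        conf = confusion_by_score(scores, outcomes)
        auc, _, _ = auc_trapezoid(
            roc_from_confusion(conf), int(outcomes.sum()), int(n - outcomes.sum())
        )
        pos = scores[outcomes == 1]
        neg = scores[outcomes == 0]
        u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)


def test_display_proportion_convention():
    """Interior proportions are never displayed as 0.00 or 1.00."""
    assert display_proportion(2353 / 2359) == 0.99  # rounds to 1.00 raw
    assert display_proportion(0.004) == 0.01
    assert display_proportion(1.0) == 1.0
    assert display_proportion(0.0) == 0.0
    assert display_proportion(0.87234) == 0.87
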