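"""Age cut-point search, item selection, cut-off rule, and subject scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from riskscreen import (
    CoxFit,
    ToolSpec,
    score_cohort,
    score_subject,
    select_age_cutoff,
    select_score_cutoff,
)
from riskscreen.errors import NoSplitError, ScoringError, ToolBuildError
from riskscreen.toolbuild import assemble_tool, split_chi2
from conftest import fixture_confusion


# ---------------------------------------------------------------------------
# Age cut-point search

def test_split_chi2_matches_hand_computation():
    # two age groups: events (3, 4), exposures (10, 40) person-years
    # total events 7 over 50 py -> expected (7*10/50, 7*40/50) = (1.4, 5.6)
    # chi2 = (3-1.4)^2/1.4 + (4-5.6)^2/5.6 = 1.828571428... + 0.457142857...
    hand = (3 - 1.4) ** 2 / 1.4 + (4 - 5.6) ** 2 / 5.6
    assert split_chi2([3, 4], [10, 40]) == pytest.approx(hand, abs=1e-10)


def test_age_search_four_row_toy_statistic_exact():
    """The search reproduces hand-computed chi-squares at each candidate."""
    ages = np.array([20.0, 20.0, 40.0, 40.0])
    events = np.array([3, 1, 1, 2])
    exposures = np.array([10.0, 12.0, 8.0, 20.0])
    res = select_age_cutoff(ages, events, exposures, min_exposure_frac=0.0)
    # single candidate at (20+40)/2 = 30: below has 4 events / 22 py,
    # above 3 events / 28 py; total 7 events over 50 py
    e_below = 7 * 22.0 / 50.0
    e_above = 7 * 28.0 / 50.0
    hand = (4 - e_below) ** 2 / e_below + (3 - e_above) ** 2 / e_above
    assert res.threshold == pytest.approx(30.0)
    assert res.n_candidates == 1
    assert res.chi2 == pytest.approx(hand, abs=1e-10)


def test_age_search_no_events_errors():
    with pytest.raises(NoSplitError, match="no events"):
        select_age_cutoff([20, 30, 40], [0, 0, 0], [1.0, 1.0, 1.0])


def test_age_search_identical_ages_errors():
    with pytest.raises(NoSplitError, match="identical"):
        select_age_cutoff([25, 25, 25], [1, 0, 1], [1.0, 1.0, 1.0])


def test_age_search_null_reports_unsupported_split(rng):
    """When conviction rate does not depend on age, the Bonferroni-adjusted
    best split is non-significant but an argmax is still reported."""
    n = 3000
    ages = rng.uniform(15, 54, n)
    exposures = rng.exponential(8.0, n)
    events = (rng.random(n) < 0.1).astype(int)  # independent of age
    res = select_age_cutoff(ages, events, exposures)
    assert not res.split_supported
    assert 15 < res.threshold < 54
    assert res.p_bonferroni > 0.05


def test_age_search_ties_break_toward_smaller_threshold():
    # two candidates with identical chi2 by symmetry
    ages = np.array([10.0, 20.0, 30.0, 40.0])
    events = np.array([2, 0, 0, 2])
    exposures = np.array([5.0, 5.0, 5.0, 5.0])
    res = select_age_cutoff(ages, events, exposures, min_exposure_frac=0.0)
    chi_lo = split_chi2([2, 2], [5.0, 15.0])
    chi_hi = split_chi2([2, 2], [15.0, 5.0])
    assert chi_lo == pytest.approx(chi_hi)
    assert res.threshold == pytest.approx(15.0)  # midpoint of 10 and 20


# ---------------------------------------------------------------------------
# Item selection

def _fake_fit(names, coef, se):
    return CoxFit(
        covariates=list(names),
        coef=np.array(coef, float),
        se=np.array(se, float),
        loglik=0.0,
        ties="efron",
    )


def test_all_significant_candidates_yield_five_item_tool():
    fit = _fake_fit(
        ["male", "prior_conviction", "young_age", "alcohol", "drug"],
        np.log([3.3, 3.3, 1.9, 2.9, 3.5]),
        [0.1] * 5,
    )
    tool = assemble_tool(fit, age_threshold=32.0)
    assert tool.items == ["male", "prior_conviction", "young_age", "alcohol", "drug"]
    assert tool.age_threshold == 32.0


def test_null_candidate_dropped():
    fit = _fake_fit(["male", "low_education"], [1.2, 0.05], [0.1, 0.2])
    tool = assemble_tool(fit, age_threshold=32.0)
    assert tool.items == ["male"]


def test_no_surviving_items_is_build_error():
    fit = _fake_fit(["male"], [0.01], [0.5])
    with pytest.raises(ToolBuildError):
        assemble_tool(fit, age_threshold=32.0)


# ---------------------------------------------------------------------------
# Score cut-off rule

@pytest.mark.parametrize("horizon", [1, 2, 5])
def test_sensitivity_floor_selects_cutoff_two(horizon):
    conf = fixture_confusion(horizon)
    assert select_score_cutoff(conf, 0.85) == 2


def test_floor_of_one_forces_cutoff_zero(confusion_1y):
    assert select_score_cutoff(confusion_1y, 1.0) == 0


def test_cutoff_nonincreasing_in_floor(confusion_1y):
    cuts = [select_score_cutoff(confusion_1y, f) for f in np.linspace(0.01, 1.0, 60)]
    assert all(a >= b for a, b in zip(cuts, cuts[1:]))


@given(floor=st.floats(min_value=0.01, max_value=1.0))
def test_cutoff_sensitivity_meets_floor_property(floor):
    conf = fixture_confusion(1)
    c = select_score_cutoff(conf, floor)
    sens = conf.set_index("cutoff").eval("tp / (tp + fn)")
    if c > 0:
        assert sens.loc[c] >= floor
    if c < 5:
        assert sens.loc[c + 1] < floor


# ---------------------------------------------------------------------------
# Subject scoring

def _subject(**kw):
    base = {
        "id": "s1",
        "male": 0,
        "prior_conviction": 0,
        "age_at_assessment": 40.0,
        "alcohol": 0,
        "drug": 0,
    }
    base.update(kw)
    return base


def test_young_male_screens_in():
    rs = score_subject(_subject(male=1, age_at_assessment=24.0), ToolSpec())
    assert rs.score == 2
    assert rs.decision == "screen_in"
    assert not rs.override_applied


def test_older_female_with_no_factors_screens_out():
    rs = score_subject(_subject(), ToolSpec())
    assert rs.score == 0
    assert rs.decision == "screen_out"


def test_override_forces_screen_in_never_out():
    rs = score_subject(_subject(), ToolSpec(), override=True)
    assert rs.score == 0
    assert rs.decision == "screen_in"
    assert rs.override_applied
    # override on an already screened-in subject changes nothing
    rs2 = score_subject(_subject(male=1, age_at_assessment=20.0), ToolSpec(), override=True)
    assert rs2.decision == "screen_in"
    assert not rs2.override_applied


def test_age_threshold_is_strict():
    tool = ToolSpec()
    assert score_subject(_subject(age_at_assessment=32.0), tool).score == 0
    assert score_subject(_subject(age_at_assessment=31.999), tool).score == 1


def test_missing_field_names_the_field():
    subject = _subject()
    del subject["alcohol"]
    with pytest.raises(ScoringError, match="alcohol"):
        score_subject(subject, ToolSpec())


def test_scoring_invariant_to_item_order(small_cohort):
    a = ToolSpec()
    b = ToolSpec(items=list(reversed(a.items)))
    np.testing.assert_array_equal(score_cohort(small_cohort, a), score_cohort(small_cohort, b))


def test_toolspec_validation():
    with pytest.raises(ValueError):
        ToolSpec(items=["male", "male"])
    with pytest.raises(ValueError):
        ToolSpec(score_cutoff=6)
    with pytest.raises(ValueError):
        ToolSpec(sensitivity_floor=0.0)


def test_toolspec_json_roundtrip(tmp_path):
    tool = ToolSpec(score_cutoff=2, sensitivity_floor=0.85)
    path = tmp_path / "tool.json"
    tool.to_json(path)
    assert ToolSpec.from_json(path) == tool


@pytest.mark.parametrize("horizon", [1, 2, 5])
def test_sensitivity_and_specificity_monotone_in_cutoff(horizon):
    conf = fixture_confusion(horizon)
    sens = (conf["tp"] / (conf["tp"] + conf["fn"])).to_numpy()
    spec = (conf["tn"] / (conf["tn"] + conf["fp"])).to_numpy()
    assert np.all(np.diff(sens) <= 1e-12)
    assert np.all(np.diff(spec) >= -1e-12)
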