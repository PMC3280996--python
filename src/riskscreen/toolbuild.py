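"""Construction of the unit-scored screening tool.

Covers the exposure-adjusted chi-square search for the age cut-point, item
selection from the joint Cox fit, the sensitivity-floor rule for the score
cut-off, and subject scoring with the clinical-override provision (override
can only force a screen-in, never a screen-out).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NoSplitError, ScoringError, ToolBuildError
from .survival import CoxFit
from .synth_cohort import _as_frame

DEFAULT_SENSITIVITY_FLOOR = 0.85


# ---------------------------------------------------------------------------
# Age cut-point search

@dataclass
class AgeCutoffResult:
    """Outcome of the exposure-adjusted single-split search over age."""

    threshold: float
    chi2: float
    p_bonferroni: float
    n_candidates: int
    split_supported: bool


def select_age_cutoff(
    ages,
    events,
    exposures,
    alpha: float = 0.05,
    min_exposure_frac: float = 0.01,
) -> AgeCutoffResult:
    """Find the age threshold that best separates conviction rates.

    Candidate thresholds are midpoints of adjacent distinct ages.  At each
    candidate a 2x2 of observed events versus person-time-expected events
    under a common rate is formed (rate adjustment through exposure offsets)
    and the Pearson chi-square computed; the returned threshold maximises the
    statistic, ties broken toward the smaller threshold.  The p-value is
    Bonferroni-penalised by the number of candidates; ``split_supported`` is
    False when even the best split is non-significant at ``alpha``.

    Candidates leaving less than ``min_exposure_frac`` of total exposure on
    either side are excluded to avoid degenerate edge splits.
    """
    ages = np.asarray(ages, dtype=float)
    events = np.asarray(events, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    if events.sum() < 1:
        raise NoSplitError("no events: cannot search for an age cut-off")
    uniq = np.unique(ages)
    if uniq.size < 2:
        raise NoSplitError("all ages identical: no candidate thresholds")

    order = np.argsort(ages, kind="stable")
    a_sorted = ages[order]
    # cumulative events / exposure strictly below each candidate midpoint
    cum_ev = np.cumsum(events[order])
    cum_ex = np.cumsum(exposures[order])
    # last index at which age == uniq[j]
    last_idx = np.searchsorted(a_sorted, uniq, side="right") - 1
    thresholds = 0.5 * (uniq[:-1] + uniq[1:])
    ev_below = cum_ev[last_idx[:-1]]
    ex_below = cum_ex[last_idx[:-1]]

    tot_ev = events.sum()
    tot_ex = exposures.sum()
    keep = (ex_below >= min_exposure_frac * tot_ex) & (
        tot_ex - ex_below >= min_exposure_frac * tot_ex
    )
    if not keep.any():
        keep = np.ones_like(thresholds, dtype=bool)
    thresholds, ev_below, ex_below = thresholds[keep], ev_below[keep], ex_below[keep]

    exp_below = tot_ev * ex_below / tot_ex
    exp_above = tot_ev - exp_below
    ev_above = tot_ev - ev_below
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (ev_below - exp_below) ** 2 / exp_below + (
            ev_above - exp_above
        ) ** 2 / exp_above
    chi2 = np.where(np.isfinite(chi2), chi2, 0.0)

    best = int(np.argmax(chi2))  # argmax returns the first (smallest) maximiser
    k = len(thresholds)
    p = min(1.0, k * float(stats.chi2.sf(chi2[best], df=1)))
    return AgeCutoffResult(
        threshold=float(thresholds[best]),
        chi2=float(chi2[best]),
        p_bonferroni=p,
        n_candidates=k,
        split_supported=p < alpha,
    )


def split_chi2(events, exposures) -> float:
    """Exposure-adjusted Pearson chi-square for a fixed two-group split.

    ``events`` and ``exposures`` are length-2 (below, at-or-above); expected
    events allocate the total in proportion to person-time.
    """
    ev = np.asarray(events, dtype=float)
    ex = np.asarray(exposures, dtype=float)
    expected = ev.sum() * ex / ex.sum()
    return float(((ev - expected) ** 2 / expected).sum())


# ---------------------------------------------------------------------------
# Tool specification and scoring

@dataclass
class ToolSpec:
    """A unit-scored screening tool: +1 per item present, screen in at
    ``score >= score_cutoff``.

    The ``young_age`` item is the predicate ``age_at_assessment <
    age_threshold`` (strict); every other item is a binary indicator column
    of the same name.
    """

    items: list[str] = field(
        default_factory=lambda: ["male", "prior_conviction", "young_age", "alcohol", "drug"]
    )
    age_threshold: float = 32.0
    score_cutoff: int = 2
    sensitivity_floor: float = DEFAULT_SENSITIVITY_FLOOR
    override_allowed: bool = True

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("tool items must have distinct names")
        if not 0 <= self.score_cutoff <= len(self.items):
            raise ValueError("score_cutoff outside [0, n_items]")
        if not 0 < self.sensitivity_floor <= 1:
            raise ValueError("sensitivity_floor must be in (0, 1]")

    def required_fields(self) -> list[str]:
        return [
            "age_at_assessment" if name == "young_age" else name
            for name in self.items
        ]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ToolSpec":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class RiskScore:
    subject_id: str
    score: int
    decision: str  # "screen_in" | "screen_out"
    override_applied: bool = False


def assemble_tool(
    cox_fit: CoxFit,
    age_threshold: float,
    sensitivity_floor: float = DEFAULT_SENSITIVITY_FLOOR,
    alpha: float = 0.05,
    score_cutoff: int | None = None,
) -> ToolSpec:
    """Build a unit-scored tool from the covariates that remain significant
    independent predictors (two-sided Wald p < ``alpha``) in the joint fit.

    ``score_cutoff`` defaults to 0 (i.e. "everyone screens in") until
    :func:`select_score_cutoff` chooses one from a confusion table.
    """
    p = cox_fit.p_values
    items = [name for name, pv in zip(cox_fit.covariates, p) if pv < alpha]
    if not items:
        raise ToolBuildError("no covariate survived selection; cannot build a tool")
    return ToolSpec(
        items=items,
        age_threshold=age_threshold,
        score_cutoff=0 if score_cutoff is None else score_cutoff,
        sensitivity_floor=sensitivity_floor,
    )


def select_score_cutoff(confusion: pd.DataFrame, sensitivity_floor: float) -> int:
    """Largest cut-off whose sensitivity still meets the floor; 0 if none.

    ``confusion`` must carry one row per cut-off with columns ``cutoff``,
    ``tp`` and ``fn`` (as produced by the accuracy module).
    """
    sens = confusion["tp"] / (confusion["tp"] + confusion["fn"])
    ok = confusion.loc[sens >= sensitivity_floor, "cutoff"]
    return int(ok.max()) if len(ok) else 0


def _item_value(record, name: str, age_threshold: float) -> int:
    field_name = "age_at_assessment" if name == "young_age" else name
    try:
        value = record[field_name]
    except (KeyError, IndexError):
        raise ScoringError(f"subject record is missing field {field_name!r}") from None
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ScoringError(f"subject record is missing field {field_name!r}")
    if name == "young_age":
        return int(float(value) < age_threshold)
    return int(value)


def score_subject(subject, tool: ToolSpec, override: bool = False) -> RiskScore:
    """Score one subject record and apply the cut-off decision.

    The clinical override, when allowed by the tool, forces a screen-in
    regardless of score; it can never force a screen-out.
    """
    score = sum(_item_value(subject, name, tool.age_threshold) for name in tool.items)
    screen_in = score >= tool.score_cutoff
    override_applied = bool(override and tool.override_allowed and not screen_in)
    decision = "screen_in" if (screen_in or override_applied) else "screen_out"
    try:
        sid = str(subject["id"])
    except (KeyError, IndexError):
        sid = ""
    return RiskScore(sid, int(score), decision, override_applied)


def score_cohort(cohort, tool: ToolSpec) -> np.ndarray:
    """Vectorised integer scores for every subject in the cohort."""
    df = _as_frame(cohort)
    for f in tool.required_fields():
        if f not in df.columns:
            raise ScoringError(f"cohort is missing field {f!r}")
    total = np.zeros(len(df), dtype=np.int64)
    for name in tool.items:
        if name == "young_age":
            total += (
                df["age_at_assessment"].to_numpy(dtype=float) < tool.age_threshold
            ).astype(np.int64)
        else:
            total += df[name].to_numpy(dtype=np.int64)
    return total
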