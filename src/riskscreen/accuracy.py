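"""Horizon-specific contingency tables and diagnostic-accuracy statistics.

Implements the at-risk exclusion rule (subjects censored event-free before
the horizon are dropped, so per-horizon 2x2 tables are well defined), the
four outcome statistics — sensitivity/specificity/NPV/PPV, the diagnostic
odds ratio, and the trapezoidal AUC with its Hanley–McNeil standard error —
and the Bayes projection of predictive values onto hypothetical base rates.

Confidence intervals: Wilson score for proportions, log-normal for the DOR,
Wald with Hanley–McNeil SE for the AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateTableError, UndefinedValueError
from .synth_cohort import _as_frame


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed-table rounding."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def display_proportion(x: float) -> float:
    """Two-decimal display value for a proportion in a screening table.

    Proportions that are not exactly 0 or 1 are never displayed as 0.00 or
    1.00 — a screen with false negatives must not be printed as perfect — so
    interior values are clipped to [0.01, 0.99] after half-up rounding.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"proportion outside [0, 1]: {x}")
    if x == 0.0 or x == 1.0:
        return x
    return min(max(round_half_up(x, 2), 0.01), 0.99)


@dataclass
class ContingencyTable:
    """TP/FP/TN/FN counts at a given follow-up horizon and score cut-off."""

    tp: int
    fp: int
    tn: int
    fn: int
    horizon: float | None = None
    cutoff: int | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def base_rate(self) -> float:
        return (self.tp + self.fn) / self.n


@dataclass
class AccuracyReport:
    """Point estimates with 95% CIs; ``screened_out`` is TN + FN."""

    sensitivity: float
    specificity: float
    npv: float
    ppv: float
    dor: float
    base_rate: float
    n: int
    screened_out: int
    ci: dict[str, tuple[float, float]]
    auc: float | None = None
    auc_se: float | None = None

    def to_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "npv": self.npv,
            "ppv": self.ppv,
            "dor": self.dor,
            "base_rate": self.base_rate,
            "n": self.n,
            "screened_out": self.screened_out,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }
        if self.auc is not None:
            out["auc"] = self.auc
            out["auc_se"] = self.auc_se
        return out


@dataclass
class RocCurve:
    """Empirical ROC: (FPR, TPR) per score threshold, anchored at (0,0), (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if self.fpr.shape != self.tpr.shape:
            raise ValueError("fpr and tpr must have equal length")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")


def at_risk_subset(cohort, horizon: float) -> pd.DataFrame:
    """Subjects evaluable at the horizon.

    Keeps subjects convicted within the horizon (positives) and subjects
    followed at least to the horizon (at-risk negatives); drops event-free
    subjects censored earlier by death, emigration or end of follow-up.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    df = _as_frame(cohort)
    f = df["followup_years"]
    keep = ((df["event"] == 1) & (f <= horizon)) | (f >= horizon)
    return df.loc[keep].reset_index(drop=True)


def outcome_at_horizon(df: pd.DataFrame, horizon: float) -> np.ndarray:
    """1 for subjects convicted within the horizon, else 0."""
    return (
        (df["event"].to_numpy() == 1)
        & (df["followup_years"].to_numpy() <= horizon)
    ).astype(np.int64)


def confusion_by_score(
    scores, outcomes, horizon: float | None = None, max_score: int = 5
) -> pd.DataFrame:
    """Cumulative TP/TN/FP/FN per cut-off, treating score >= cutoff as positive.

    The cut-off-0 row classifies everyone positive (sensitivity 1.00,
    specificity 0.00).
    """
    scores = np.asarray(scores, dtype=np.int64)
    outcomes = np.asarray(outcomes, dtype=np.int64)
    if scores.min() < 0 or scores.max() > max_score:
        raise ValueError(f"scores must lie in 0..{max_score}")
    n_pos = int(outcomes.sum())
    n_neg = int(len(outcomes) - n_pos)
    rows = []
    for c in range(max_score + 1):
        positive = scores >= c
        tp = int(np.sum(positive & (outcomes == 1)))
        fp = int(np.sum(positive & (outcomes == 0)))
        rows.append(
            {
                "cutoff": c,
                "tp": tp,
                "tn": n_neg - fp,
                "fp": fp,
                "fn": n_pos - tp,
                "sensitivity": tp / n_pos if n_pos else np.nan,
                "specificity": (n_neg - fp) / n_neg if n_neg else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["horizon"] = horizon
    return out


def confusion_from_fixture(counts: pd.DataFrame, horizon: float | None = None) -> pd.DataFrame:
    """Confusion-by-cutoff table from per-score offender/non-offender counts."""
    scores = np.repeat(counts["score"].to_numpy(), counts["offenders"] + counts["nonoffenders"])
    outcomes = np.concatenate(
        [
            np.repeat([1, 0], [off, non])
            for off, non in zip(counts["offenders"], counts["nonoffenders"])
        ]
    )
    return confusion_by_score(scores, outcomes, horizon=horizon)


def table_row(confusion: pd.DataFrame, cutoff: int, horizon: float | None = None) -> ContingencyTable:
    rec = confusion.loc[confusion["cutoff"] == cutoff]
    if rec.empty:
        raise ValueError(f"cutoff {cutoff} not present in confusion table")
    rec = rec.iloc[0]
    return ContingencyTable(
        tp=int(rec["tp"]),
        fp=int(rec["fp"]),
        tn=int(rec["tn"]),
        fn=int(rec["fn"]),
        horizon=horizon if horizon is not None else confusion.attrs.get("horizon"),
        cutoff=cutoff,
    )


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def accuracy_summary(ct: ContingencyTable, continuity: bool = False) -> AccuracyReport:
    """Sensitivity, specificity, NPV, PPV and DOR with 95% CIs.

    Proportion CIs are Wilson score intervals; the DOR CI is log-normal,
    ``exp(ln DOR +/- 1.96 * sqrt(1/tp + 1/fp + 1/tn + 1/fn))``.  A zero
    FP x FN product leaves the DOR undefined unless ``continuity`` enables
    the Haldane–Anscombe +0.5 correction.
    """
    tp, fp, tn, fn = ct.tp, ct.fp, ct.tn, ct.fn
    for name, denom in (
        ("sensitivity", tp + fn),
        ("specificity", tn + fp),
        ("npv", tn + fn),
        ("ppv", tp + fp),
    ):
        if denom == 0:
            raise UndefinedValueError(f"{name} denominator is zero")

    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    npv = tn / (tn + fn)
    ppv = tp / (tp + fp)

    if fp * fn == 0 or tp * tn == 0:
        if not continuity:
            raise DegenerateTableError(
                "DOR undefined with a zero cell; enable the continuity "
                "correction to add 0.5 to every cell"
            )
        a, b, c, d = tp + 0.5, fp + 0.5, tn + 0.5, fn + 0.5
    else:
        a, b, c, d = float(tp), float(fp), float(tn), float(fn)
    dor = (a * c) / (b * d)
    log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    ci = {
        "sensitivity": _wilson(tp, tp + fn),
        "specificity": _wilson(tn, tn + fp),
        "npv": _wilson(tn, tn + fn),
        "ppv": _wilson(tp, tp + fp),
        "dor": (dor * math.exp(-z * log_se), dor * math.exp(z * log_se)),
    }
    return AccuracyReport(
        sensitivity=se,
        specificity=sp,
        npv=npv,
        ppv=ppv,
        dor=dor,
        base_rate=ct.base_rate,
        n=ct.n,
        screened_out=tn + fn,
        ci=ci,
    )


def roc_from_confusion(confusion: pd.DataFrame) -> RocCurve:
    """Empirical ROC from a confusion-by-cutoff table, anchored at (0,0)."""
    fpr = 1.0 - confusion["specificity"].to_numpy(dtype=float)
    tpr = confusion["sensitivity"].to_numpy(dtype=float)
    order = np.lexsort((tpr, fpr))  # FPR ties ordered by TPR
    fpr, tpr = fpr[order], tpr[order]
    if fpr[0] > 0 or tpr[0] > 0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    if fpr[-1] < 1 or tpr[-1] < 1:
        fpr = np.concatenate([fpr, [1.0]])
        tpr = np.concatenate([tpr, [1.0]])
    return RocCurve(fpr, tpr)


def auc_trapezoid(
    roc: RocCurve, n_pos: int, n_neg: int
) -> tuple[float, float, tuple[float, float]]:
    """Trapezoidal AUC with Hanley–McNeil SE and 95% Wald CI.

    The Hanley–McNeil variance uses Q1 = A/(2-A) and Q2 = 2A^2/(1+A) with
    ``n_pos`` cases and ``n_neg`` non-cases.
    """
    if roc.fpr.size < 2:
        raise ValueError("ROC needs at least two points")
    auc = float(np.trapezoid(roc.tpr, roc.fpr))
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.975)
    return auc, se, (auc - z * se, auc + z * se)


def project_predictive_values(
    se: float, sp: float, base_rate: float
) -> tuple[float, float]:
    """PPV and NPV at a hypothetical base rate, by Bayes' theorem.

    ``ppv = se*pi / (se*pi + (1-sp)(1-pi))`` and
    ``npv = sp(1-pi) / (sp(1-pi) + (1-se)*pi)``.  At ``pi = 0`` the NPV is
    exactly 1 and the PPV exactly 0.
    """
    for name, v in (("se", se), ("sp", sp), ("base_rate", base_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {v}")
    pi = base_rate
    if pi == 0.0:
        return 0.0, 1.0
    ppv_den = se * pi + (1 - sp) * (1 - pi)
    npv_den = sp * (1 - pi) + (1 - se) * pi
    if ppv_den == 0 or npv_den == 0:
        raise UndefinedValueError("predictive value undefined: zero denominator")
    return se * pi / ppv_den, sp * (1 - pi) / npv_den
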