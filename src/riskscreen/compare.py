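"""Shrinkage and incremental-validity comparisons.

Three tests, matching the study's comparison battery: Pearson chi-square for
a difference between two proportions, the Breslow–Day chi-square for
homogeneity of odds ratios across strata, and the Hanley–McNeil z test for a
difference between AUCs estimated on independent samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

ALPHA = 0.05


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    df: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> ComparisonResult:
    """Pearson chi-square (df 1, no continuity correction) on the pooled 2x2."""
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample size must be positive")
        if not 0 <= x <= n:
            raise ValueError("count outside [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() == 0:
        # both samples all-success or all-failure: proportions identical
        return ComparisonResult(statistic=0.0, p_value=1.0, df=1)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ComparisonResult(statistic=float(chi2), p_value=float(p), df=1)


def mantel_haenszel_or(tables) -> float:
    """Mantel–Haenszel common odds ratio across 2x2 strata."""
    num = sum(t[0][0] * t[1][1] / _total(t) for t in tables)
    den = sum(t[0][1] * t[1][0] / _total(t) for t in tables)
    if den == 0:
        raise ValueError("Mantel-Haenszel denominator is zero")
    return num / den


def _total(t) -> float:
    return float(t[0][0] + t[0][1] + t[1][0] + t[1][1])


def expected_cell(table, psi: float) -> float:
    """Expected top-left cell of a 2x2 with fixed margins under odds ratio psi.

    Solves the quadratic ``A(n - r1 - c1 + A) = psi (r1 - A)(c1 - A)`` and
    returns the root inside the admissible range
    ``[max(0, r1 + c1 - n), min(r1, c1)]``.
    """
    a, b = float(table[0][0]), float(table[0][1])
    c, d = float(table[1][0]), float(table[1][1])
    r1, c1 = a + b, a + c
    n = a + b + c + d
    if psi == 1.0:
        return r1 * c1 / n
    # (1 - psi) A^2 + [psi (r1 + c1) - r1 - c1 + n] A - psi r1 c1 = 0
    qa = 1.0 - psi
    qb = psi * (r1 + c1) - r1 - c1 + n
    qc = -psi * r1 * c1
    disc = math.sqrt(qb * qb - 4 * qa * qc)
    lo_adm = max(0.0, r1 + c1 - n)
    hi_adm = min(r1, c1)
    for root in ((-qb + disc) / (2 * qa), (-qb - disc) / (2 * qa)):
        if lo_adm - 1e-9 <= root <= hi_adm + 1e-9:
            return float(np.clip(root, lo_adm, hi_adm))
    raise ValueError("no admissible root for the expected cell")


def breslow_day(tables, tarone: bool = False) -> ComparisonResult:
    """Breslow–Day chi-square for homogeneity of odds ratios.

    ``tables`` is a sequence of K >= 2 2x2 arrays (rows: exposure, columns:
    outcome).  The statistic sums ``(a_k - A_k)^2 / Var(A_k)`` where ``A_k``
    is the expected exposed-case cell under the Mantel–Haenszel common odds
    ratio; df = K - 1.  ``tarone=True`` applies Tarone's correction term.
    """
    tables = [np.asarray(t, dtype=float) for t in tables]
    if len(tables) < 2:
        raise ValueError("need at least two strata")
    for t in tables:
        if t.shape != (2, 2):
            raise ValueError("each stratum must be a 2x2 table")
        if (t.sum(axis=0).min() == 0) or (t.sum(axis=1).min() == 0):
            raise ValueError("degenerate margins in a stratum")
    psi = mantel_haenszel_or(tables)
    stat = 0.0
    resid_sum = 0.0
    var_sum = 0.0
    for t in tables:
        a = t[0, 0]
        r1, c1 = t[0].sum(), t[:, 0].sum()
        n = t.sum()
        ea = expected_cell(t, psi)
        var = 1.0 / (
            1.0 / ea
            + 1.0 / (r1 - ea)
            + 1.0 / (c1 - ea)
            + 1.0 / (n - r1 - c1 + ea)
        )
        stat += (a - ea) ** 2 / var
        resid_sum += a - ea
        var_sum += var
    if tarone:
        stat -= resid_sum**2 / var_sum
    df = len(tables) - 1
    return ComparisonResult(
        statistic=float(stat), p_value=float(stats.chi2.sf(stat, df)), df=df
    )


def auc_difference_test(
    auc1: float, se1: float, auc2: float, se2: float
) -> ComparisonResult:
    """Hanley–McNeil z for AUCs from independent samples."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (auc1 - auc2) / math.sqrt(se1**2 + se2**2)
    return ComparisonResult(
        statistic=float(z), p_value=float(2.0 * stats.norm.sf(abs(z))), df=None
    )
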