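"""Proportional-hazards fitting and person-time utilities.

Used for two things: selecting the screening items (covariates that remain
significant independent predictors of violent conviction in the joint Cox
model) and validating that the simulator's planted hazard ratios are
recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .errors import ConvergenceError
from .synth_cohort import _as_frame

# |beta| above this on a binary covariate signals a monotone partial
# likelihood (perfect separation) rather than a real effect.
_SEPARATION_BETA = 15.0


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    Hazard ratios are ``exp(beta)``; confidence intervals are Wald intervals
    ``exp(beta +/- 1.96 * SE)``.
    """

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    ties: str

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def conf_int(self) -> np.ndarray:
        """(k, 2) array of 95% CI bounds on the hazard-ratio scale."""
        z = stats.norm.ppf(0.975)
        return np.exp(
            np.column_stack([self.coef - z * self.se, self.coef + z * self.se])
        )

    @property
    def p_values(self) -> np.ndarray:
        """Two-sided Wald p-values."""
        return 2.0 * stats.norm.sf(np.abs(self.coef) / self.se)

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hazard_ratios,
                "hr_lo": ci[:, 0],
                "hr_hi": ci[:, 1],
                "p": self.p_values,
            },
            index=self.covariates,
        )

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "loglik": float(self.loglik),
            "ties": self.ties,
        }


def fit_cox(cohort, covariates: list[str], ties: str = "efron") -> CoxFit:
    """Fit a Cox model of time to violent conviction on the given covariates.

    Parameters
    ----------
    cohort
        Cohort or schema frame with ``followup_years`` and ``event``.
    covariates
        Column names to enter jointly.
    ties
        Tie-handling method, ``"efron"`` (default) or ``"breslow"``.

    Raises
    ------
    ValueError
        If a covariate is constant or there are no events.
    ConvergenceError
        On a monotone partial likelihood (perfect separation) or
        non-convergence.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method: {ties!r}")
    df = _as_frame(cohort)
    if int(df["event"].sum()) < 1:
        raise ValueError("cohort contains no events")
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariates not in cohort schema: {missing}")
    X = df[covariates].to_numpy(dtype=float)
    for j, name in enumerate(covariates):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant across subjects")

    model = PHReg(
        df["followup_years"].to_numpy(dtype=float),
        X,
        status=df["event"].to_numpy(dtype=int),
        ties=ties,
    )
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # separation is diagnosed from the estimates below, not the warning
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(coef)) or not np.all(np.isfinite(se)):
        raise ConvergenceError("non-finite estimates: partial likelihood may be monotone")
    scale = np.std(X, axis=0)
    if np.any(se > 1e3) or np.any(
        np.abs(coef) * np.maximum(scale, 1e-12) > _SEPARATION_BETA
    ):
        raise ConvergenceError(
            "implausibly large coefficient: monotone partial likelihood "
            "(perfect separation) suspected"
        )
    return CoxFit(
        covariates=list(covariates),
        coef=coef,
        se=se,
        loglik=float(model.loglike(coef)),
        ties=ties,
    )


def person_years(cohort, horizon: float) -> float:
    """Total exposure within the horizon: sum of min(followup, horizon)."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    f = _as_frame(cohort)["followup_years"].to_numpy(dtype=float)
    return float(np.minimum(f, horizon).sum())
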