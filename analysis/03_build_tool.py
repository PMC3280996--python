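#!/usr/bin/env python
"""Build the unit-scored screening tool on the calibration sample.

Three steps on the calibration half of the simulated cohort: (1) the
exposure-adjusted chi-square search for the age cut-point, (2) retention of
covariates that remain significant independent predictors in the joint Cox
model, (3) the sensitivity-floor rule (floor 0.85) for the score cut-off
across the 1-, 2- and 5-year horizons.  The frozen tool is written to
results/tool.json.

Run:  python analysis/03_build_tool.py [--seed N]
"""

import argparse
from pathlib import Path

from riskscreen import (
    PRIMARY_ITEMS,
    assemble_tool,
    fit_cox,
    score_cohort,
    select_age_cutoff,
    select_score_cutoff,
    split_cohort,
)
from riskscreen import accuracy as acc

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    import importlib.util
    spec = importlib.util.spec_from_file_location("fit02", Path(__file__).parent / "02_fit_hazards.py")
    fit02 = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(fit02)

    cohort = fit02.load_cohort(args.seed)
    cal, _ = split_cohort(cohort, n_replicates=3, seed=args.seed)

    age = select_age_cutoff(cal["age_at_assessment"], cal["event"], cal["followup_years"])
    print(f"age cut-point search: threshold {age.threshold:.1f} years "
          f"(chi2 {age.chi2:.1f}, Bonferroni p {age.p_bonferroni:.2e}, "
          f"{age.n_candidates} candidates, supported={age.split_supported})")

    cal = cal.copy()
    cal["young_age"] = (cal["age_at_assessment"] < age.threshold).astype(int)
    fit = fit_cox(cal, PRIMARY_ITEMS)
    tool = assemble_tool(fit, age.threshold, sensitivity_floor=0.85)
    print(f"items surviving selection (Wald p < 0.05): {', '.join(tool.items)}")

    cuts = []
    for h in (1, 2, 5):
        sub = acc.at_risk_subset(cal, h)
        conf = acc.confusion_by_score(
            score_cohort(sub, tool), acc.outcome_at_horizon(sub, h),
            horizon=h, max_score=len(tool.items),
        )
        cuts.append(select_score_cutoff(conf, 0.85))
        print(f"  horizon {h}y: sensitivity-floor cut-off {cuts[-1]}")
    tool.score_cutoff = int(min(cuts))
    print(f"frozen score cut-off: {tool.score_cutoff} (screen in at score >= "
          f"{tool.score_cutoff})")

    (ROOT / "results").mkdir(exist_ok=True)
    tool.to_json(ROOT / "results" / "tool.json")
    print("tool written to results/tool.json")


if __name__ == "__main__":
    main()
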