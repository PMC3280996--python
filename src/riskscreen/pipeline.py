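"""End-to-end study orchestration.

Runs the full stepped-screening study: simulate (or inject printed-count
fixtures), split into calibration and replication samples, search the age
cut-point, select items from the joint Cox fit, choose the score cut-off on
the calibration sample, freeze the tool, evaluate every sample at every
horizon, test for shrinkage, and sweep predictive values across base rates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import accuracy as acc
from . import compare as cmp
from .errors import RiskscreenError
from .survival import fit_cox
from .synth_cohort import (
    Cohort,
    SimConfig,
    PRIMARY_ITEMS,
    fixture_cohort,
    generate_cohort,
    TABLE2_CUMULATIVE,
)
from .toolbuild import (
    DEFAULT_SENSITIVITY_FLOOR,
    ToolSpec,
    assemble_tool,
    score_cohort,
    select_age_cutoff,
    select_score_cutoff,
)

logger = logging.getLogger("riskscreen")

DEFAULT_HORIZONS = (1, 2, 5)
DEFAULT_BASE_RATES = (0.02, 0.04, 0.06, 0.08, 0.10)


@dataclass
class StudyConfig:
    """Run configuration for :func:`run_study`.

    ``mode`` is ``"simulate"`` (generate a cohort under ``sim``) or
    ``"fixture"`` (evaluate the calibration sample reconstructed from the
    printed per-score counts; no replicates, no shrinkage section).
    """

    mode: str = "simulate"
    sim: SimConfig = field(default_factory=SimConfig)
    n_replicates: int = 3
    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    sensitivity_floor: float = DEFAULT_SENSITIVITY_FLOOR
    base_rates: tuple[float, ...] = DEFAULT_BASE_RATES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "fixture"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.n_replicates < 0:
            raise ValueError("n_replicates must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["horizons"] = list(self.horizons)
        d["base_rates"] = list(self.base_rates)
        return d

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if "sim" in raw:
            sim = dict(raw["sim"])
            for key in ("age_iqr", "age_bounds"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["sim"] = SimConfig(**sim)
        for key in ("horizons", "base_rates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class StudyReport:
    """Everything the study computes, traceable back to stored counts."""

    tool: ToolSpec
    age_search: dict | None
    samples: dict  # sample -> horizon -> {confusion, table, report}
    base_rate_sweep: dict  # horizon -> {pi -> {"ppv":, "npv":}}
    shrinkage: dict  # horizon -> replicate -> {test -> ComparisonResult dict}
    provenance: dict

    def to_dict(self, include_timestamp: bool = False) -> dict:
        prov = dict(self.provenance)
        if not include_timestamp:
            prov.pop("timestamp", None)
        samples = {}
        for sample, horizons in self.samples.items():
            samples[sample] = {}
            for h, blocks in horizons.items():
                samples[sample][str(h)] = {
                    "confusion": blocks["confusion"].to_dict(orient="records"),
                    "table": asdict(blocks["table"]),
                    "report": blocks["report"].to_dict(),
                }
        return {
            "tool": asdict(self.tool),
            "age_search": self.age_search,
            "samples": samples,
            "base_rate_sweep": {
                str(h): {f"{pi:.2f}": v for pi, v in grid.items()}
                for h, grid in self.base_rate_sweep.items()
            },
            "shrinkage": {
                str(h): {
                    rep: {name: r for name, r in tests.items()}
                    for rep, tests in reps.items()
                }
                for h, reps in self.shrinkage.items()
            },
            "provenance": prov,
        }

    def to_json(self, path, include_timestamp: bool = False) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(include_timestamp), fh, indent=2, sort_keys=True)
            fh.write("\n")


def split_cohort(cohort, n_replicates: int, seed: int):
    """Random disjoint, exhaustive split into calibration + equal replicates.

    Calibration receives half the cohort (floor) plus any remainder not
    divisible among the replicates; replicates are equal-sized thirds (or
    ``n_replicates``-ths) of the rest.  Reproducible under ``seed``.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    n = len(df)
    if n < 2 * max(n_replicates, 1):
        raise ValueError("cohort too small to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = n // 2
    pool = n - n_cal
    if n_replicates > 0:
        rep_size = pool // n_replicates
        leftover = pool - rep_size * n_replicates
        if leftover:
            logger.info("split_cohort: %d leftover subjects assigned to calibration", leftover)
        n_cal += leftover
    else:
        rep_size = 0
        n_cal = n
    cal = df.iloc[perm[:n_cal]].reset_index(drop=True)
    reps = [
        df.iloc[perm[n_cal + k * rep_size : n_cal + (k + 1) * rep_size]].reset_index(drop=True)
        for k in range(n_replicates)
    ]
    return cal, reps


def _evaluate_sample(df: pd.DataFrame, tool: ToolSpec, horizon: float) -> dict:
    """At-risk subset -> scores -> confusion table -> accuracy + AUC."""
    sub = acc.at_risk_subset(df, horizon)
    scores = score_cohort(sub, tool)
    outcomes = acc.outcome_at_horizon(sub, horizon)
    confusion = acc.confusion_by_score(scores, outcomes, horizon=horizon)
    table = acc.table_row(confusion, tool.score_cutoff, horizon=horizon)
    # small replication samples can produce zero-cell tables; the continuity
    # correction only engages when a cell is actually zero
    report = acc.accuracy_summary(table, continuity=True)
    roc = acc.roc_from_confusion(confusion)
    n_pos = int(outcomes.sum())
    n_neg = int(len(outcomes) - n_pos)
    auc, se, ci = acc.auc_trapezoid(roc, n_pos, n_neg)
    report.auc, report.auc_se = auc, se
    report.ci["auc"] = ci
    return {"confusion": confusion, "table": table, "report": report}


def incremental_validity(
    df: pd.DataFrame, tool: ToolSpec, extra_item: str, horizons=DEFAULT_HORIZONS
) -> dict:
    """Does adding ``extra_item`` to the tool improve discrimination?

    Compares trapezoidal AUCs of the base and extended scores at each
    horizon with the Hanley–McNeil z test; the item is judged to improve the
    tool only if the extended AUC is higher with p < 0.05 at >= 1 horizon.
    """
    extended = ToolSpec(
        items=tool.items + [extra_item],
        age_threshold=tool.age_threshold,
        score_cutoff=tool.score_cutoff,
        sensitivity_floor=tool.sensitivity_floor,
    )
    per_horizon = {}
    improved = False
    for h in horizons:
        sub = acc.at_risk_subset(df, h)
        outcomes = acc.outcome_at_horizon(sub, h)
        n_pos, n_neg = int(outcomes.sum()), int(len(outcomes) - outcomes.sum())
        aucs = {}
        for label, t, m in (("base", tool, len(tool.items)), ("extended", extended, len(extended.items))):
            conf = acc.confusion_by_score(score_cohort(sub, t), outcomes, max_score=m)
            roc = acc.roc_from_confusion(conf)
            aucs[label] = acc.auc_trapezoid(roc, n_pos, n_neg)
        res = cmp.auc_difference_test(
            aucs["extended"][0], aucs["extended"][1], aucs["base"][0], aucs["base"][1]
        )
        gain = aucs["extended"][0] > aucs["base"][0] and res.significant
        improved = improved or gain
        per_horizon[h] = {
            "auc_base": aucs["base"][0],
            "auc_extended": aucs["extended"][0],
            "test": res.to_dict(),
            "improves": gain,
        }
    return {"item": extra_item, "improves_any_horizon": improved, "per_horizon": per_horizon}


def _stage(name: str, start: float, **info) -> None:
    details = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - start, details)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the whole study and return a :class:`StudyReport`.

    Any stage failure is re-raised annotated with the stage name and the
    config hash.  The tool (age threshold, items, cut-off) is estimated on
    the calibration sample only and applied frozen to every replicate.
    """
    stage = "setup"
    try:
        if config.mode == "fixture":
            return _run_fixture_study(config)

        stage = "simulate"
        t0 = time.perf_counter()
        cohort = generate_cohort(config.sim)
        _stage(stage, t0, n=len(cohort), seed=config.sim.seed)

        stage = "split"
        t0 = time.perf_counter()
        cal, reps = split_cohort(cohort, config.n_replicates, config.seed)
        _stage(stage, t0, calibration=len(cal), replicates=[len(r) for r in reps])

        stage = "age_cutpoint"
        t0 = time.perf_counter()
        age_search = select_age_cutoff(
            cal["age_at_assessment"], cal["event"], cal["followup_years"]
        )
        _stage(stage, t0, threshold=f"{age_search.threshold:.1f}")

        stage = "item_selection"
        t0 = time.perf_counter()
        cal = cal.copy()
        cal["young_age"] = (
            cal["age_at_assessment"] < age_search.threshold
        ).astype(int)
        fit = fit_cox(cal, PRIMARY_ITEMS)
        tool = assemble_tool(
            fit, age_search.threshold, sensitivity_floor=config.sensitivity_floor
        )
        _stage(stage, t0, items=",".join(tool.items))

        stage = "cutoff_selection"
        t0 = time.perf_counter()
        per_h = []
        for h in config.horizons:
            sub = acc.at_risk_subset(cal, h)
            conf = acc.confusion_by_score(
                score_cohort(sub, tool), acc.outcome_at_horizon(sub, h), horizon=h,
                max_score=len(tool.items),
            )
            per_h.append(select_score_cutoff(conf, config.sensitivity_floor))
        # most sensitivity-protective cut-off across horizons
        tool.score_cutoff = int(min(per_h))
        _stage(stage, t0, per_horizon=per_h, chosen=tool.score_cutoff)

        stage = "evaluation"
        t0 = time.perf_counter()
        sample_frames = {"calibration": cal}
        for k, rep in enumerate(reps, start=1):
            sample_frames[f"replicate_{k}"] = rep
        samples = {
            name: {h: _evaluate_sample(frame, tool, h) for h in config.horizons}
            for name, frame in sample_frames.items()
        }
        _stage(stage, t0, samples=len(samples))

        stage = "shrinkage"
        t0 = time.perf_counter()
        shrinkage = _shrinkage_tests(samples, config.horizons)
        _stage(stage, t0)

        stage = "base_rate_sweep"
        t0 = time.perf_counter()
        sweep = _base_rate_sweep(samples, config.horizons, config.base_rates)
        _stage(stage, t0, rates=list(config.base_rates))

        provenance = {
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "seed": config.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        return StudyReport(
            tool=tool,
            age_search=asdict(age_search),
            samples=samples,
            base_rate_sweep=sweep,
            shrinkage=shrinkage,
            provenance=provenance,
        )
    except RiskscreenError as exc:
        raise type(exc)(
            f"stage {stage!r} failed (config {config.hash()}): {exc}"
        ) from exc


def _run_fixture_study(config: StudyConfig) -> StudyReport:
    """Calibration-only study on the printed-count fixture cohorts."""
    horizons = [h for h in config.horizons if h in TABLE2_CUMULATIVE]
    tool = ToolSpec(
        score_cutoff=0, sensitivity_floor=config.sensitivity_floor
    )
    per_h = []
    frames = {}
    for h in horizons:
        frames[h] = fixture_cohort(h).data
        sub = acc.at_risk_subset(frames[h], h)
        conf = acc.confusion_by_score(
            score_cohort(sub, tool), acc.outcome_at_horizon(sub, h), horizon=h
        )
        per_h.append(select_score_cutoff(conf, config.sensitivity_floor))
    tool.score_cutoff = int(min(per_h))
    samples = {
        "calibration": {h: _evaluate_sample(frames[h], tool, h) for h in horizons}
    }
    sweep = _base_rate_sweep(samples, horizons, config.base_rates)
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return StudyReport(
        tool=tool,
        age_search=None,
        samples=samples,
        base_rate_sweep=sweep,
        shrinkage={},
        provenance=provenance,
    )


def _shrinkage_tests(samples: dict, horizons) -> dict:
    """Calibration vs each replicate: NPV-complement chi-square, Breslow–Day
    on the screen-decision x outcome tables, and the Hanley–McNeil AUC z."""
    out: dict = {}
    if "calibration" not in samples:
        return out
    replicate_names = [s for s in samples if s.startswith("replicate_")]
    for h in horizons:
        cal_block = samples["calibration"][h]
        ct_cal = cal_block["table"]
        rep_cal = cal_block["report"]
        out[h] = {}
        for rep_name in replicate_names:
            blk = samples[rep_name][h]
            ct = blk["table"]
            rep = blk["report"]
            npv_test = cmp.two_proportion_test(
                ct_cal.fn, ct_cal.fn + ct_cal.tn, ct.fn, ct.fn + ct.tn
            )
            strata = [
                [[ct_cal.tp, ct_cal.fp], [ct_cal.fn, ct_cal.tn]],
                [[ct.tp, ct.fp], [ct.fn, ct.tn]],
            ]
            # same continuity policy as the DOR: +0.5 everywhere if any cell
            # of either stratum is empty
            if min(min(min(r) for r in t) for t in strata) == 0:
                strata = [[[c + 0.5 for c in r] for r in t] for t in strata]
            dor_test = cmp.breslow_day(strata)
            auc_test = cmp.auc_difference_test(
                rep_cal.auc, rep_cal.auc_se, rep.auc, rep.auc_se
            )
            out[h][rep_name] = {
                "npv_complement": npv_test.to_dict(),
                "dor_homogeneity": dor_test.to_dict(),
                "auc_difference": auc_test.to_dict(),
            }
    return out


def _base_rate_sweep(samples: dict, horizons, base_rates) -> dict:
    sweep: dict = {}
    for h in horizons:
        rep = samples["calibration"][h]["report"]
        sweep[h] = {}
        for pi in base_rates:
            ppv, npv = acc.project_predictive_values(
                rep.sensitivity, rep.specificity, pi
            )
            sweep[h][pi] = {"ppv": ppv, "npv": npv}
    return sweep


# ---------------------------------------------------------------------------
# Table rendering

def _fmt2(x: float) -> str:
    return f"{acc.round_half_up(x, 2):.2f}"


def _fmtp(x: float) -> str:
    return f"{acc.display_proportion(x):.2f}"


def _table2_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for h, blocks in report.samples["calibration"].items():
        conf = blocks["confusion"]
        for _, r in conf.iterrows():
            rows.append(
                {
                    "horizon_years": h,
                    "cutoff": int(r["cutoff"]),
                    "tp": int(r["tp"]),
                    "tn": int(r["tn"]),
                    "fp": int(r["fp"]),
                    "fn": int(r["fn"]),
                    "sensitivity": _fmtp(r["sensitivity"]),
                    "specificity": _fmtp(r["specificity"]),
                }
            )
    return pd.DataFrame(rows)


def _table3_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for sample, horizons in report.samples.items():
        for h, blocks in horizons.items():
            r = blocks["report"]
            rows.append(
                {
                    "horizon_years": h,
                    "sample": sample,
                    "n": r.n,
                    "npv": _fmtp(r.npv),
                    "ppv": _fmtp(r.ppv),
                    "dor": _fmt2(r.dor),
                    "auc": _fmt2(r.auc),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["horizon_years", "sample"]).reset_index(drop=True)


def _table4_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for h, grid in report.base_rate_sweep.items():
        for stat in ("npv", "ppv"):
            row = {"horizon_years": h, "statistic": stat.upper()}
            for pi, vals in grid.items():
                row[f"base_rate_{int(round(pi * 100))}pct"] = _fmtp(vals[stat])
            rows.append(row)
    return pd.DataFrame(rows)


def _to_markdown(frame: pd.DataFrame) -> str:
    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def render_tables(report: StudyReport, outdir, fmt: str = "csv") -> list:
    """Write table2/table3/table4 files mirroring the published layout.

    ``fmt`` is ``csv``, ``json`` or ``markdown``; output is deterministic
    for a fixed report.  An empty base-rate grid omits table4 with a logged
    notice.  Returns the paths written.
    """
    from pathlib import Path

    if fmt not in ("csv", "json", "markdown"):
        raise ValueError(f"unknown format: {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {"table2": _table2_frame(report), "table3": _table3_frame(report)}
    t4 = _table4_frame(report)
    if t4.empty:
        logger.info("render_tables: base-rate grid empty, table4 omitted")
    else:
        frames["table4"] = t4
    ext = {"csv": "csv", "json": "json", "markdown": "md"}[fmt]
    paths = []
    for name, frame in frames.items():
        path = outdir / f"{name}.{ext}"
        if fmt == "csv":
            frame.to_csv(path, index=False)
        elif fmt == "json":
            frame.to_json(path, orient="records", indent=2)
        else:
            path.write_text(_to_markdown(frame), encoding="utf-8")
        paths.append(path)
    return paths
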