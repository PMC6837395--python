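"""Orchestration: schema validation, the four analyses, JSON reports.

``run_analysis`` runs testability, normative, repeatability and diagnostic
analyses over a cohort table (plus an optional retest table), each on its
own sample filter, and returns a JSON-serializable report containing raw
values alongside display-rounded ones (integer percentages, 2-decimal log
quantities).  Every child of the input is accounted for per analysis as
either analyzed or excluded-with-reason.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from typing import Sequence

import numpy as np
import pandas as pd

from . import diagnostics as dx
from . import normative, repeatability as rp, threshold_stats as ts
from ._util import round_half_up
from .scores import NOT_TESTABLE, ScoreError, parse_score

__all__ = [
    "AnalysisConfig",
    "ValidationError",
    "validate_table",
    "read_cohort_csv",
    "read_retest_csv",
    "run_analysis",
    "report_to_json",
]

COHORT_COLUMNS = [
    "child_id",
    "age_years",
    "sex",
    "testable",
    "score",
    "cover_test",
    "acuity_right",
    "acuity_left",
    "parent_report_bv",
    "questionnaire_returned",
    "glasses_needed",
    "glasses_worn",
]

RETEST_COLUMNS = ["child_id", "age_years", "sex", "score_session1", "score_session2"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full analysis run."""

    bv: dx.BVConfig = field(default_factory=dx.BVConfig)
    age_transform: str = "log10_months"
    fit_norms: bool = True
    percentiles: tuple[float, ...] = ts.DEFAULT_PERCENTILES
    fit_seed: int = 0


class ValidationError(ValueError):
    """Raised when an input table fails schema validation."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            f"{len(self.errors)} validation error(s); first: {self.errors[0]}"
        )


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[""], dtype={"score": str})


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (missing values as empty strings)."""
    df = _read_csv(path)
    errors = validate_table(df)
    if errors:
        raise ValidationError(errors)
    return df


def read_retest_csv(path) -> pd.DataFrame:
    """Read and validate a retest CSV."""
    df = pd.read_csv(
        path,
        keep_default_na=False,
        na_values=[""],
        dtype={"score_session1": str, "score_session2": str},
    )
    errors = validate_retest_table(df)
    if errors:
        raise ValidationError(errors)
    return df


def _check_score(token, row: int, col: str, errors: list[str]) -> None:
    try:
        parse_score(token)
    except ScoreError as exc:
        errors.append(f"row {row}, {col}: {exc}")


def validate_table(records: pd.DataFrame) -> list[str]:
    """Schema-check a cohort table; returns ALL violations with row numbers."""
    errors: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in records.columns]
    if missing:
        return [f"missing columns: {missing}"]
    for i, row in records.iterrows():
        age = row["age_years"]
        try:
            age = float(age)
            if not 2.0 <= age <= 12.0:
                errors.append(f"row {i}, age_years: {age} outside [2, 12]")
        except (TypeError, ValueError):
            errors.append(f"row {i}, age_years: not a number ({age!r})")
        if str(row["sex"]).upper() not in ("M", "F"):
            errors.append(f"row {i}, sex: must be M or F, got {row['sex']!r}")
        _check_score(row["score"], i, "score", errors)
        cover = str(row["cover_test"]).strip().lower() if pd.notna(row["cover_test"]) else ""
        if cover not in ("", "pass", "heterotropia", "nan"):
            errors.append(
                f"row {i}, cover_test: must be pass/heterotropia/empty, got {cover!r}"
            )
        for col in ("acuity_right", "acuity_left"):
            v = row[col]
            if pd.isna(v) or v == "":
                continue  # missing acuity is legal (e.g. nursery-age children)
            try:
                v = float(v)
                if not -0.3 <= v <= 2.0:
                    errors.append(f"row {i}, {col}: {v} outside [-0.3, 2.0] logMAR")
            except (TypeError, ValueError):
                errors.append(f"row {i}, {col}: not a number ({v!r})")
    return errors


def validate_retest_table(records: pd.DataFrame) -> list[str]:
    """Schema-check a retest table."""
    errors: list[str] = []
    missing = [c for c in RETEST_COLUMNS if c not in records.columns]
    if missing:
        return [f"missing columns: {missing}"]
    for i, row in records.iterrows():
        for col in ("score_session1", "score_session2"):
            _check_score(row[col], i, col, errors)
    return errors


# ---------------------------------------------------------------------------
# Analysis sections


def _parsed_scores(series: pd.Series) -> list:
    return [parse_score(s) for s in series]


def _summary_dict(s: ts.ScoreSummary) -> dict:
    return {
        "n_tested": s.n_tested,
        "pct_nil": s.pct_nil,
        "pct_nil_display": round_half_up(s.pct_nil, 1),
        "log_mean": s.log_mean,
        "log_sd": s.log_sd,
        "log_mean_display": None if s.log_mean is None else round_half_up(s.log_mean, 2),
        "log_sd_display": None if s.log_sd is None else round_half_up(s.log_sd, 2),
        "linear_mean": s.linear_mean,
        "linear_sd": s.linear_sd,
        "percentiles": {str(p): str(v) for p, v in s.percentiles.items()},
    }


def _testability_section(cohort: pd.DataFrame) -> dict:
    table = dx.testability_summary(cohort)
    return {
        "by_group": table.reset_index().to_dict(orient="records"),
        "overall_pct": round_half_up(
            100.0 * cohort["testable"].astype(bool).mean()
        ),
        "n": len(cohort),
    }


def _norms_section(cohort: pd.DataFrame, config: AnalysisConfig) -> dict:
    subset, log = dx.filter_normative(cohort, config.bv)
    section: dict = {
        "n_input": len(cohort),
        "n_analyzed": len(subset),
        "n_excluded": len(cohort) - len(subset),
        "exclusion_log": log,
        "by_group": {},
    }
    groups = dx.assign_age_group(subset["age_years"])
    for name, _, _ in dx.NORMS_AGE_GROUPS:
        grp = subset[(groups == name).to_numpy()]
        if grp.empty:
            continue
        section["by_group"][name] = _summary_dict(
            ts.summarize_scores(_parsed_scores(grp["score"]), config.percentiles)
        )
    if len(subset):
        section["all"] = _summary_dict(
            ts.summarize_scores(_parsed_scores(subset["score"]), config.percentiles)
        )
    if config.fit_norms and len(subset) > 20:
        A = normative.age_covariate(
            subset["age_years"].to_numpy(dtype=float), config.age_transform
        )
        male = (
            subset["sex"].astype(str).str.upper().str.startswith("M").to_numpy(float)
        )
        fit = normative.fit_ordinal(
            _parsed_scores(subset["score"]),
            np.column_stack([A, male]),
            feature_names=("beta", "gamma"),
            seed=config.fit_seed,
            age_transform=config.age_transform,
        )
        section["fit"] = {
            "estimates": dict(zip(fit.param_names, fit.estimates.tolist())),
            "standard_errors": dict(
                zip(fit.param_names, fit.standard_errors.tolist())
            ),
            "p_values": dict(zip(fit.param_names, fit.p_values.tolist())),
            "deviance": fit.deviance,
            "n": fit.n,
            "converged": fit.converged,
            "age_transform": config.age_transform,
        }
    return section


def _ba_dict(r: rp.BlandAltmanResult) -> dict:
    return {
        "n": r.n,
        "bias": r.bias,
        "sd_diff": r.sd_diff,
        "loa": r.loa,
        "loa_display": round_half_up(r.loa, 2),
        "loa_ci": list(r.loa_ci),
        "loa_factor": r.loa_factor,
        "bias_t": None if math.isnan(r.bias_t) else r.bias_t,
        "bias_p": None if math.isnan(r.bias_p) else r.bias_p,
        "zero_variance": r.zero_variance,
    }


def _agreement_dict(a: rp.AgreementTable) -> dict:
    return {
        "n": a.n,
        "pass_pass": a.pass_pass,
        "pass_fail": a.pass_fail,
        "fail_pass": a.fail_pass,
        "fail_fail": a.fail_fail,
        "pct_agree": a.pct_agree,
        "pct_agree_display": round_half_up(a.pct_agree),
        "pearson_r": a.pearson_r,
        "spearman_rho": a.spearman_rho,
    }


def _repeatability_section(retest: pd.DataFrame) -> dict:
    usable = retest[
        (retest["score_session1"].map(parse_score) != NOT_TESTABLE)
        & (retest["score_session2"].map(parse_score) != NOT_TESTABLE)
    ]
    pairs = [
        rp.RetestPair(
            child_id=str(r.child_id),
            score1=parse_score(r.score_session1),
            score2=parse_score(r.score_session2),
            age_years=float(r.age_years),
            sex=str(r.sex),
        )
        for r in usable.itertuples()
    ]
    section: dict = {
        "n_input": len(retest),
        "n_analyzed": len(pairs),
        "n_excluded": len(retest) - len(pairs),
        "by_group": {},
    }
    if len(pairs) < 3:
        section["note"] = "too few pairs for Bland-Altman analysis"
        return section
    ages = np.array([p.age_years for p in pairs])
    groups = dx.assign_age_group(pd.Series(ages))
    for name, _, _ in dx.NORMS_AGE_GROUPS:
        sel = [p for p, g in zip(pairs, groups) if g == name]
        if len(sel) < 3:
            continue
        entry = {"bland_altman": _ba_dict(rp.bland_altman(sel))}
        entry["agreement"] = _agreement_dict(rp.agreement_table(sel))
        section["by_group"][name] = entry
    section["all"] = {
        "bland_altman": _ba_dict(rp.bland_altman(pairs)),
        "agreement": _agreement_dict(rp.agreement_table(pairs)),
    }
    diffs = np.array(
        [rp.to_log_threshold(p.score2) - rp.to_log_threshold(p.score1) for p in pairs]
    )
    young, old = diffs[ages < 5.0], diffs[ages >= 5.0]
    if young.size >= 2 and old.size >= 2 and np.var(old, ddof=1) > 0:
        F, dfs, p = rp.variance_ratio_test(young, old)
        section["variance_ratio_under5_vs_5plus"] = {
            "F": F,
            "df": list(dfs),
            "p": p,
        }
    if len(pairs) > 3:
        try:
            ols = rp.abs_diff_regression(pairs)
            section["abs_diff_regression"] = {
                "coefficients": dict(zip(ols.model.exog_names, ols.params.tolist())),
                "p_values": dict(zip(ols.model.exog_names, ols.pvalues.tolist())),
            }
        except ValueError as exc:
            section["abs_diff_regression"] = {"note": str(exc)}
    return section


def _metrics_dict(counts: dx.ConfusionCounts) -> dict:
    metrics = dx.confusion_metrics(counts)
    return {
        "n": counts.n,
        "tp": counts.tp,
        "fp": counts.fp,
        "tn": counts.tn,
        "fn": counts.fn,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "ppv": metrics.ppv,
        "npv": metrics.npv,
        "display": metrics.rounded(),
    }


def _diagnostics_section(cohort: pd.DataFrame, config: AnalysisConfig) -> dict:
    subset, log = dx.filter_validity(cohort)
    section: dict = {
        "n_input": len(cohort),
        "n_analyzed": len(subset),
        "n_excluded": len(cohort) - len(subset),
        "exclusion_log": log,
        "by_group": {},
    }
    if subset.empty:
        return section
    parsed = subset.copy()
    parsed["score"] = _parsed_scores(subset["score"])
    groups = dx.assign_age_group(parsed["age_years"], dx.DIAG_AGE_GROUPS)
    for name, _, _ in dx.DIAG_AGE_GROUPS:
        grp = parsed[(groups == name).to_numpy()]
        if grp.empty:
            continue
        counts = dx.confusion_from_frame(grp, config.bv)
        if counts.n:
            section["by_group"][name] = _metrics_dict(counts)
    section["all"] = _metrics_dict(dx.confusion_from_frame(parsed, config.bv))
    return section


def run_analysis(
    cohort: pd.DataFrame,
    retest: pd.DataFrame | None = None,
    config: AnalysisConfig = AnalysisConfig(),
    metadata: dict | None = None,
) -> dict:
    """Run all four analyses over a validated cohort (and optional retest) table.

    Deterministic given inputs and config.  When no retest table is given
    the repeatability section is replaced by a notice, not an error.
    """
    errors = validate_table(cohort)
    if errors:
        raise ValidationError(errors)
    report = {
        "metadata": {
            "package": "randotkit",
            "version": _package_version(),
            "generated": datetime.datetime.now(datetime.timezone.utc).isoformat(
                timespec="seconds"
            ),
            "config": dataclasses.asdict(config),
            **(metadata or {}),
        },
        "testability": _testability_section(cohort),
        "norms": _norms_section(cohort, config),
        "diagnostics": _diagnostics_section(cohort, config),
    }
    if retest is None:
        report["repeatability"] = {"note": "no retest table provided"}
    else:
        errors = validate_retest_table(retest)
        if errors:
            raise ValidationError(errors)
        report["repeatability"] = _repeatability_section(retest)
    return report


def _package_version() -> str:
    try:
        return version("randotkit")
    except PackageNotFoundError:
        return "unknown"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def report_to_json(report: dict, indent: int = 2) -> str:
    """Serialize a report dict to JSON (NaN -> null, numpy -> native)."""
    return json.dumps(_jsonable(report), indent=indent)
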