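"""Case classification, sample filters, testability counts and 2x2 accuracy.

A child is classified as having a binocular vision (BV) problem when any of
four criteria fires, applied in a strict precedence order:

1. ``Parent`` — the parental questionnaire clearly indicates strabismus,
   amblyopia or ongoing eye-clinic assessment;
2. ``CTFAIL`` — the cover test found heterotropia;
3. ``ModVI`` — acuity in the worse eye exceeds 0.48 logMAR (the WHO
   "moderate visual impairment" cut-off);
4. ``IADonly`` — interocular acuity difference exceeds 0.2 logMAR with no
   other abnormality.

Each category therefore subsumes the ones below it; a child failing the
cover test is CTFAIL regardless of acuity.  Missing questionnaires count as
"no parental report" rather than excluding the child.

The stereotest is treated as a binary screen: pass = any numeric score
(800 arcsec or better), fail = nil.  Sensitivity, specificity, PPV and NPV
follow from the resulting 2x2 table.

Two sample filters mirror the analysis samples:

- the *normative* filter keeps apparently visually normal, testable
  children (cover-test pass required; acuity rules applied from age 4);
- the *validity* filter keeps every testable child with a usable reference
  standard (cover test performed; acuity measured from age 4), including
  the cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import round_half_up
from .scores import NIL, NOT_TESTABLE, ScoreError, StereoScore, score_rank

__all__ = [
    "BVConfig",
    "BVCategory",
    "ConfusionCounts",
    "DiagnosticMetrics",
    "classify_bv_problem",
    "classify_bv_frame",
    "stereo_fail",
    "confusion_metrics",
    "confusion_from_frame",
    "filter_normative",
    "filter_validity",
    "testability_summary",
    "assign_age_group",
    "NORMS_AGE_GROUPS",
    "DIAG_AGE_GROUPS",
]

#: BV-problem categories in precedence order (strongest evidence first).
BV_CATEGORIES = ("Parent", "CTFAIL", "ModVI", "IADonly", "none")
BVCategory = str


@dataclass(frozen=True)
class BVConfig:
    """Thresholds for the acuity-based classification criteria (logMAR)."""

    modvi_threshold: float = 0.48  # worse-eye acuity, strict >
    iad_threshold: float = 0.2  # interocular difference, strict >


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def classify_bv_problem(
    record: Mapping, config: BVConfig = BVConfig()
) -> BVCategory:
    """Classify one child record into a BV-problem category.

    Expects mapping keys ``parent_report_bv`` (yes/no/missing),
    ``cover_test`` (pass/heterotropia/missing) and ``acuity_right`` /
    ``acuity_left`` (logMAR or missing).  Missing fields make the
    corresponding criterion evaluate to "no".
    """
    if str(record.get("parent_report_bv", "")).strip().lower() == "yes":
        return "Parent"
    if str(record.get("cover_test", "")).strip().lower() == "heterotropia":
        return "CTFAIL"
    right, left = record.get("acuity_right"), record.get("acuity_left")
    if not _is_missing(right) and not _is_missing(left):
        right, left = float(right), float(left)
        if max(right, left) > config.modvi_threshold:
            return "ModVI"
        if abs(right - left) > config.iad_threshold:
            return "IADonly"
    return "none"


def classify_bv_frame(
    records: pd.DataFrame, config: BVConfig = BVConfig()
) -> pd.Series:
    """Vectorized :func:`classify_bv_problem` over a cohort DataFrame."""
    parent = (
        records["parent_report_bv"].astype(str).str.strip().str.lower() == "yes"
    )
    ctfail = records["cover_test"].astype(str).str.strip().str.lower() == "heterotropia"
    right = pd.to_numeric(records["acuity_right"], errors="coerce")
    left = pd.to_numeric(records["acuity_left"], errors="coerce")
    both = right.notna() & left.notna()
    worse = np.maximum(right, left)
    iad = (right - left).abs()
    modvi = both & (worse > config.modvi_threshold)
    iadonly = both & (iad > config.iad_threshold)
    out = pd.Series("none", index=records.index, dtype=object)
    out[iadonly] = "IADonly"
    out[modvi] = "ModVI"
    out[ctfail] = "CTFAIL"
    out[parent] = "Parent"
    return out


def stereo_fail(score: StereoScore) -> bool:
    """True iff the child failed the stereotest outright (scored nil)."""
    if score == NOT_TESTABLE:
        raise ScoreError("NOT_TESTABLE children cannot be scored pass/fail")
    score_rank(score)  # validates
    return score == NIL


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts: positives fail the stereotest, cases have a BV problem."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV as raw percentages.

    A metric with a zero denominator is None (unavailable), never 0 or 100.
    ``rounded()`` gives the integer display form (half-up).
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def rounded(self) -> dict[str, int | None]:
        return {
            k: (None if v is None else int(round_half_up(v)))
            for k, v in self.__dict__.items()
        }


def confusion_metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Diagnostic accuracy metrics from a 2x2 table."""
    if counts.n == 0:
        raise ValueError("all-zero confusion table")

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return DiagnosticMetrics(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
        ppv=ratio(counts.tp, counts.tp + counts.fp),
        npv=ratio(counts.tn, counts.tn + counts.fn),
    )


def confusion_from_frame(
    records: pd.DataFrame, config: BVConfig = BVConfig()
) -> ConfusionCounts:
    """Classify a validity-filtered cohort and cross-tabulate against pass/fail."""
    case = classify_bv_frame(records, config) != "none"
    fail = records["score"].map(stereo_fail)
    return ConfusionCounts(
        tp=int((case & fail).sum()),
        fp=int((~case & fail).sum()),
        tn=int((~case & ~fail).sum()),
        fn=int((case & ~fail).sum()),
    )


# ---------------------------------------------------------------------------
# Sample filters


def _acuity_cols(records: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    right = pd.to_numeric(records["acuity_right"], errors="coerce")
    left = pd.to_numeric(records["acuity_left"], errors="coerce")
    return right, left


def _apply_rules(
    records: pd.DataFrame, rules: list[tuple[str, pd.Series]]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows by the first rule that fires; log counts per rule."""
    excluded = pd.Series(False, index=records.index)
    log: dict[str, int] = {}
    for name, mask in rules:
        fires = mask & ~excluded
        log[name] = int(fires.sum())
        excluded |= fires
    return records.loc[~excluded].copy(), log


def filter_normative(
    records: pd.DataFrame, config: BVConfig = BVConfig()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Select the apparently visually normal sample for normative analysis.

    Keeps testable children who passed the cover test, had no parental
    report of a BV problem, and were not recorded as needing but not
    wearing glasses.  From age 4, acuity must be available, no worse than
    0.2 logMAR in either eye, and differ by at most ``iad_threshold``
    between eyes.  Children with missing questionnaires are kept.

    Returns (subset, exclusion log).  Idempotent: filtering a filtered
    sample excludes nothing further.
    """
    testable = records["testable"].astype(bool)
    cover = records["cover_test"].astype(str).str.strip().str.lower()
    parent = records["parent_report_bv"].astype(str).str.strip().str.lower()
    needed = records["glasses_needed"].astype(str).str.strip().str.lower()
    worn = records["glasses_worn"].astype(str).str.strip().str.lower()
    right, left = _acuity_cols(records)
    age4 = pd.to_numeric(records["age_years"]) >= 4.0
    worse = np.maximum(right, left)
    iad = (right - left).abs()
    rules = [
        ("not_testable", ~testable),
        ("cover_test_failed", cover == "heterotropia"),
        ("cover_test_missing", ~cover.isin(["pass", "heterotropia"])),
        ("parent_reported_problem", parent == "yes"),
        ("glasses_needed_not_worn", (needed == "yes") & (worn != "yes")),
        ("acuity_missing", age4 & (right.isna() | left.isna())),
        ("acuity_worse_than_0.2", age4 & (worse > 0.2)),
        (
            f"iad_above_{config.iad_threshold:g}",
            age4 & (iad > config.iad_threshold),
        ),
    ]
    return _apply_rules(records, rules)


def filter_validity(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Select the sample for the sensitivity/specificity analysis.

    Requires testability and a performed cover test (either outcome); from
    age 4, acuity measured in both eyes.  Parental reports and their
    absence are both kept: the reference standard classifies children from
    whatever evidence is available.
    """
    testable = records["testable"].astype(bool)
    cover = records["cover_test"].astype(str).str.strip().str.lower()
    right, left = _acuity_cols(records)
    age4 = pd.to_numeric(records["age_years"]) >= 4.0
    rules = [
        ("not_testable", ~testable),
        ("cover_test_missing", ~cover.isin(["pass", "heterotropia"])),
        ("acuity_missing", age4 & (right.isna() | left.isna())),
    ]
    return _apply_rules(records, rules)


# ---------------------------------------------------------------------------
# Age groups and testability


#: Reporting age bands (inclusive year ranges) for testability/norms tables.
NORMS_AGE_GROUPS: tuple[tuple[str, float, float], ...] = (
    ("2yo", 2, 3),
    ("3yo", 3, 4),
    ("4yo", 4, 5),
    ("5yo", 5, 6),
    ("6-7yo", 6, 8),
    ("9-11yo", 9, 12),
)

#: Coarser bands for the diagnostic accuracy table (rare cases).
DIAG_AGE_GROUPS: tuple[tuple[str, float, float], ...] = (
    ("2-3yo", 2, 4),
    ("4-5yo", 4, 6),
    ("6-7yo", 6, 8),
    ("9-11yo", 9, 12),
)


def assign_age_group(
    age_years, groups: tuple[tuple[str, float, float], ...] = NORMS_AGE_GROUPS
) -> pd.Series:
    """Label ages with the band [lo, hi) they fall in; "" outside all bands."""
    age = pd.to_numeric(pd.Series(age_years))
    out = pd.Series("", index=age.index, dtype=object)
    for name, lo, hi in groups:
        out[(age >= lo) & (age < hi)] = name
    return out


def testability_summary(
    records: pd.DataFrame,
    groups: tuple[tuple[str, float, float], ...] = NORMS_AGE_GROUPS,
) -> pd.DataFrame:
    """Per-age-group (and per-sex) counts and % testable.

    Percentages are rounded half-up to integers for display; empty groups
    are omitted.
    """
    df = records.copy()
    df["age_group"] = assign_age_group(df["age_years"], groups).to_numpy()
    df = df[df["age_group"] != ""]
    rows = []
    for name, _, _ in groups:
        grp = df[df["age_group"] == name]
        if grp.empty:
            continue
        testable = grp["testable"].astype(bool)
        sex = grp["sex"].astype(str).str.upper().str.startswith("M")
        row = {"age_group": name, "n": len(grp)}
        row["pct_testable"] = round_half_up(100.0 * testable.mean())
        for label, mask in (("girls", ~sex), ("boys", sex)):
            row[f"n_{label}"] = int(mask.sum())
            row[f"pct_testable_{label}"] = (
                round_half_up(100.0 * testable[mask].mean()) if mask.any() else None
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("age_group")
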