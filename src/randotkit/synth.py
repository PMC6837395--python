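"""Seeded synthetic cohorts with the statistical structure the analyses assume.

The generator emulates a pediatric vision-screening study cohort:

- ages drawn from the study-style year bands (2, 3, 4, 5, 6-7, 9-11) with
  recruitment-weighted band sizes, sex approximately balanced;
- testability following a logistic curve in age whose band averages rise
  from ~65% in two-year-olds to ~100% from age six;
- Randot Preschool scores drawn from the cumulative-logit normative model
  (published reference parameters, log10-months age covariate), with a
  continuous latent log10 threshold placed uniformly inside the scored
  level's bin so that retest noise can act on it before snapping back to
  the discrete level grid;
- a ~4% prevalence of binocular vision problems; case children carry an
  observable marker (parental report, heterotropia on cover test, reduced
  worse-eye acuity, or an interocular acuity difference) and score worse
  via a latent threshold shift plus extra probability of a nil score;
- monocular logMAR acuities (measured from age 4) built from a shared
  between-eye component plus eye-specific noise;
- questionnaire return falling with age; retest sessions with a small
  practice effect and within-child log-scale noise.

Stereoblind children are represented by a latent threshold of +inf, so
they fail both retest sessions with certainty — the test is near-perfectly
reliable as a pass/fail classifier while individual thresholds fluctuate.

All randomness flows from one seeded generator; identical seeds give
byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normative import REFERENCE_PARAMS, OrdinalParams, age_covariate
from .scores import LEVELS, LOG_LEVELS, NIL, NOT_TESTABLE, StereoScore

__all__ = [
    "CohortConfig",
    "RetestConfig",
    "snap_to_level",
    "generate_cohort",
    "generate_retest",
    "config_hash",
]

#: Latent log-threshold floor used for the best level's bin (one log-step
#: below 40 arcsec, mirroring the notional nil level one step above 800).
_LOG_FLOOR = math.log10(20.0)


@dataclass(frozen=True)
class RetestConfig:
    """Retest-session structure: practice effect and within-child noise."""

    bias: float = -0.114  # session2 - session1 mean shift, log10 arcsec
    within_sd: float = 0.227  # per-session latent noise SD, log10 arcsec
    n_pairs: int = 182
    min_age_years: float = 3.0
    interval_days: float = 16.0  # descriptive only

    def validate(self) -> None:
        if self.within_sd < 0:
            raise ValueError("within_sd must be >= 0")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the anchoring study's structure: band sizes and
    testability from its recruitment tables, the published ordinal model
    for scores, ~4.1% case prevalence, and acuity moments from its
    normative-sample summaries.  ``case_latent_shift`` (log10 arcsec) and
    ``case_nil_boost`` (extra nil probability) control how much worse the
    cases score; no quantitative anchor exists for them, so they are free
    parameters set to keep the screen in the low-sensitivity /
    high-specificity regime.
    """

    n_children: int = 1005
    # (lo_year, hi_year_exclusive, recruitment weight)
    age_bands: tuple[tuple[float, float, float], ...] = (
        (2, 3, 78),
        (3, 4, 167),
        (4, 5, 171),
        (5, 6, 106),
        (6, 8, 267),
        (9, 12, 216),
    )
    sex_ratio_male: float = 488 / 1005
    # logistic in age (years); band averages ~65% at 2yo, ~92% at 3yo, 99%+
    testability_intercept: float = -3.938
    testability_slope: float = 1.823
    params: OrdinalParams = REFERENCE_PARAMS
    age_transform: str = "log10_months"
    bv_prevalence: float = 37 / 892
    case_latent_shift: float = 0.6
    case_nil_boost: float = 0.2
    # primary observable marker of a case, by category
    case_marker_probs: tuple[tuple[str, float], ...] = (
        ("Parent", 0.30),
        ("CTFAIL", 0.40),
        ("ModVI", 0.20),
        ("IADonly", 0.10),
    )
    case_secondary_parent_report: float = 0.25
    # per-eye acuity = shared N(mean, sd_shared) + eye N(0, sd_eye), from age 4
    acuity_mean_by_band: tuple[tuple[float, float, float], ...] = (
        (4, 6, 0.10),
        (6, 8, 0.07),
        (9, 12, 0.01),
    )
    acuity_sd_shared: float = 0.055
    acuity_sd_eye: float = 0.045
    acuity_min_age: float = 4.0
    cover_missing_rate: float = 0.03
    # questionnaire return, logistic in age: ~83% at 2yo falling to ~44% at 11yo
    questionnaire_intercept: float = 2.094
    questionnaire_slope: float = -0.203
    glasses_needed_rate: float = 0.08
    glasses_worn_given_needed: float = 0.85
    retest: RetestConfig = field(default_factory=RetestConfig)

    def validate(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        for p in (
            self.sex_ratio_male,
            self.bv_prevalence,
            self.case_nil_boost,
            self.cover_missing_rate,
            self.glasses_needed_rate,
            self.glasses_worn_given_needed,
            self.case_secondary_parent_report,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        weights = [w for _, _, w in self.age_bands]
        if not weights or min(weights) < 0 or sum(weights) == 0:
            raise ValueError("age band weights must be nonnegative, not all zero")
        total = sum(p for _, p in self.case_marker_probs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("case marker probabilities must sum to 1")
        self.retest.validate()


def config_hash(config: CohortConfig) -> str:
    """Short stable hash of the full configuration."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def snap_to_level(latent: float) -> StereoScore:
    """Snap a latent log10 threshold to the score the child would obtain.

    The child passes every plate at or above their true threshold, so the
    score is the smallest available level whose log10 value is >= latent;
    anything at or below log10(40) scores 40, anything above log10(800)
    scores nil.
    """
    return _snap(np.array([latent]))[0]


def _snap(latent: np.ndarray) -> list[StereoScore]:
    idx = np.searchsorted(LOG_LEVELS, latent, side="left")
    categories = list(LEVELS) + [NIL]
    return [categories[i] for i in idx]


def _latent_within_bins(cats: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Place a latent log threshold uniformly inside each scored level's bin."""
    edges = np.array([_LOG_FLOOR, *LOG_LEVELS])
    lo = edges[np.minimum(cats, len(LEVELS) - 1)]
    hi = edges[np.minimum(cats, len(LEVELS) - 1) + 1]
    latent = lo + rng.random(cats.size) * (hi - lo)
    latent[cats >= len(LEVELS)] = np.inf  # nil: stereoblind
    return latent


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort.

    Returns ``(records, truth)``: the observable per-child table (what a
    study would record) and the hidden ground truth (case status, marker,
    latent log threshold) used for validation and for retest simulation.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_children

    bands = np.array([(lo, hi) for lo, hi, _ in config.age_bands])
    weights = np.array([w for _, _, w in config.age_bands], dtype=float)
    band_idx = rng.choice(len(bands), size=n, p=weights / weights.sum())
    lo, hi = bands[band_idx, 0], bands[band_idx, 1]
    # floor to 2 decimals so rounding never pushes an age past its band edge
    age = np.floor((lo + rng.random(n) * (hi - lo)) * 100.0) / 100.0

    male = rng.random(n) < config.sex_ratio_male
    sex = np.where(male, "M", "F")

    p_testable = 1.0 / (
        1.0 + np.exp(-(config.testability_intercept + config.testability_slope * age))
    )
    testable = rng.random(n) < p_testable
    case = rng.random(n) < config.bv_prevalence

    # scores via the ordinal model, then a latent threshold inside the bin
    from .normative import sample_scores

    base_scores = sample_scores(
        config.params, age, male.astype(float), rng, config.age_transform
    )
    cats = np.array(
        [len(LEVELS) if s == NIL else LEVELS.index(s) for s in base_scores]
    )
    latent = _latent_within_bins(cats, rng)

    latent[case] += config.case_latent_shift
    boost = case & (rng.random(n) < config.case_nil_boost)
    latent[boost] = np.inf
    scores = _snap(latent)

    # observable case markers
    marker_names = [m for m, _ in config.case_marker_probs]
    marker_p = np.array([p for _, p in config.case_marker_probs])
    marker = np.where(
        case, np.array(marker_names)[rng.choice(len(marker_names), size=n, p=marker_p)], ""
    ).astype(object)
    acuity_measured = age >= config.acuity_min_age
    # acuity-based markers are undetectable where acuity is not measured
    needs_acuity = np.isin(marker, ["ModVI", "IADonly"]) & ~acuity_measured
    marker[needs_acuity] = "CTFAIL"

    # acuities: shared component + per-eye noise, case markers overriding
    acuity_mean = np.full(n, np.nan)
    for blo, bhi, mean in config.acuity_mean_by_band:
        sel = (age >= blo) & (age < bhi)
        acuity_mean[sel] = mean
    shared = acuity_mean + rng.normal(0.0, config.acuity_sd_shared, n)
    acuity_r = shared + rng.normal(0.0, config.acuity_sd_eye, n)
    acuity_l = shared + rng.normal(0.0, config.acuity_sd_eye, n)
    modvi = marker == "ModVI"
    worse_on_right = rng.random(n) < 0.5
    modvi_acuity = 0.48 + np.abs(rng.normal(0.15, 0.10, n))
    iad = marker == "IADonly"
    iad_acuity = np.minimum(
        np.minimum(acuity_r, acuity_l) + 0.25 + np.abs(rng.normal(0.05, 0.03, n)), 0.45
    )
    for sel, value in ((modvi, modvi_acuity), (iad, iad_acuity)):
        acuity_r = np.where(sel & worse_on_right, value, acuity_r)
        acuity_l = np.where(sel & ~worse_on_right, value, acuity_l)
    acuity_r = np.clip(acuity_r, -0.3, 2.0)
    acuity_l = np.clip(acuity_l, -0.3, 2.0)
    acuity_r[~acuity_measured] = np.nan
    acuity_l[~acuity_measured] = np.nan

    # cover test
    cover = np.where(
        rng.random(n) < config.cover_missing_rate, "", "pass"
    ).astype(object)
    cover[marker == "CTFAIL"] = "heterotropia"
    cover[case & (marker != "CTFAIL")] = "pass"

    # questionnaire and parental report
    p_quest = 1.0 / (
        1.0
        + np.exp(
            -(config.questionnaire_intercept + config.questionnaire_slope * age)
        )
    )
    returned = rng.random(n) < p_quest
    returned |= marker == "Parent"  # the report IS the marker
    parent_report = np.where(returned, "no", "").astype(object)
    parent_report[returned & (marker == "Parent")] = "yes"
    secondary = (
        case
        & (marker != "Parent")
        & returned
        & (rng.random(n) < config.case_secondary_parent_report)
    )
    parent_report[secondary] = "yes"

    needed = returned & (rng.random(n) < config.glasses_needed_rate)
    worn = needed & (rng.random(n) < config.glasses_worn_given_needed)
    glasses_needed = np.where(returned, np.where(needed, "yes", "no"), "").astype(object)
    glasses_worn = np.where(needed, np.where(worn, "yes", "no"), "").astype(object)

    child_id = np.array([f"c{i:05d}" for i in range(n)])
    score_col = np.array(
        [NOT_TESTABLE if not t else str(s) for t, s in zip(testable, scores)],
        dtype=object,
    )

    records = pd.DataFrame(
        {
            "child_id": child_id,
            "age_years": np.round(age, 2),
            "sex": sex,
            "testable": testable,
            "score": score_col,
            "cover_test": cover,
            "acuity_right": np.round(acuity_r, 3),
            "acuity_left": np.round(acuity_l, 3),
            "parent_report_bv": parent_report,
            "questionnaire_returned": returned,
            "glasses_needed": glasses_needed,
            "glasses_worn": glasses_worn,
        }
    )
    truth = pd.DataFrame(
        {
            "child_id": child_id,
            "age_years": np.round(age, 2),
            "sex": sex,
            "testable": testable,
            "is_case": case,
            "case_marker": marker,
            "true_log_threshold": latent,
        }
    )
    return records, truth


def generate_retest(
    truth: pd.DataFrame, config: CohortConfig, seed: int, n_pairs: int | None = None
) -> pd.DataFrame:
    """Simulate two test sessions for a retest subsample.

    Eligible children are testable and at least ``retest.min_age_years``
    old (children who could not do the test at all the first time are
    excluded from reliability analyses).  Each session's score is the
    latent true threshold plus session noise (and, on session 2, the
    practice-effect bias), snapped to the level grid.  The returned frame
    carries the pre-snap latent session values as ground truth.
    """
    rc = config.retest
    rng = np.random.default_rng(seed)
    eligible = truth[
        truth["testable"].astype(bool)
        & (pd.to_numeric(truth["age_years"]) >= rc.min_age_years)
    ]
    k = min(n_pairs if n_pairs is not None else rc.n_pairs, len(eligible))
    chosen = eligible.iloc[np.sort(rng.choice(len(eligible), size=k, replace=False))]
    t = chosen["true_log_threshold"].to_numpy(dtype=float)
    latent1 = t + rng.normal(0.0, rc.within_sd, k)
    latent2 = t + rc.bias + rng.normal(0.0, rc.within_sd, k)
    return pd.DataFrame(
        {
            "child_id": chosen["child_id"].to_numpy(),
            "age_years": chosen["age_years"].to_numpy(),
            "sex": chosen["sex"].to_numpy(),
            "score_session1": [str(s) for s in _snap(latent1)],
            "score_session2": [str(s) for s in _snap(latent2)],
            "latent_session1": latent1,
            "latent_session2": latent2,
        }
    )
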