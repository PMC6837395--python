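"""Test/retest agreement analyses for paired Randot Preschool scores.

Agreement is assessed on log10 thresholds, with a nil score replaced by a
notional 1600 arcsec (one log-level above the worst available score).  The
headline statistic is the Bland-Altman 95% limit of agreement

    L = 1.96 * s,    s = SD of (session2 - session1) log-thresholds,

whose standard error is estimated as sqrt(3 s^2 / n) and whose 95%
confidence interval as L +/- t_{0.975, n-1} * SE.  The t quantile uses
n-1 degrees of freedom; the mean difference (practice effect) is reported
and tested but, by convention here, not subtracted before computing L.

Also provided: pass/fail agreement tables (pass = any numeric level, nil =
fail) with Pearson/Spearman correlations, a two-sided F test comparing
difference variances between groups, and an OLS regression of absolute
differences on age and sex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import sample_sd
from .scores import (
    NIL,
    NIL_NOTIONAL_ARCSEC,
    NOT_TESTABLE,
    ScoreError,
    StereoScore,
    score_rank,
)

__all__ = [
    "RetestPair",
    "BlandAltmanResult",
    "AgreementTable",
    "to_log_threshold",
    "bland_altman",
    "bland_altman_from_diffs",
    "agreement_table",
    "variance_ratio_test",
    "abs_diff_regression",
]


@dataclass(frozen=True)
class RetestPair:
    """Two same-child scores from separate sessions."""

    child_id: str
    score1: StereoScore
    score2: StereoScore
    age_years: float = float("nan")
    sex: str = ""

    def __post_init__(self) -> None:
        for s in (self.score1, self.score2):
            if s == NOT_TESTABLE:
                raise ScoreError(
                    "retest pairs must have rankable scores in both sessions"
                )
            score_rank(s)  # validates


def to_log_threshold(score: StereoScore) -> float:
    """Score -> log10 threshold in log10 arcsec; nil -> log10(1600)."""
    if score == NOT_TESTABLE:
        raise ScoreError("NOT_TESTABLE has no log threshold")
    if score == NIL:
        return math.log10(NIL_NOTIONAL_ARCSEC)
    score_rank(score)  # validates level
    return math.log10(score)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman agreement between two sessions on the log scale."""

    n: int
    bias: float
    sd_diff: float
    loa: float
    loa_ci: tuple[float, float]
    loa_factor: float
    bias_t: float
    bias_p: float
    zero_variance: bool = False


def bland_altman_from_diffs(diffs: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman statistics from per-child differences (session2 - session1)."""
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    bias = float(np.mean(d))
    s = sample_sd(d)
    loa = 1.96 * s
    se_loa = math.sqrt(3.0 * s**2 / n)
    t_crit = float(stats.t.ppf(0.975, n - 1))
    ci = (loa - t_crit * se_loa, loa + t_crit * se_loa)
    zero_variance = s == 0.0
    if zero_variance:
        bias_t, bias_p = float("nan"), float("nan")
    else:
        bias_t, bias_p = stats.ttest_1samp(d, 0.0)
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=s,
        loa=loa,
        loa_ci=ci,
        loa_factor=10.0**loa,
        bias_t=float(bias_t),
        bias_p=float(bias_p),
        zero_variance=zero_variance,
    )


def _pair_logs(pairs: Sequence[RetestPair]) -> tuple[np.ndarray, np.ndarray]:
    log1 = np.array([to_log_threshold(p.score1) for p in pairs])
    log2 = np.array([to_log_threshold(p.score2) for p in pairs])
    return log1, log2


def bland_altman(pairs: Sequence[RetestPair]) -> BlandAltmanResult:
    """Bland-Altman analysis of retest pairs on log10 thresholds (nil -> 1600)."""
    log1, log2 = _pair_logs(pairs)
    return bland_altman_from_diffs(log2 - log1)


@dataclass(frozen=True)
class AgreementTable:
    """Pass/fail agreement and score correlations between two sessions.

    Pass = any numeric level (800 counts as a pass); nil = fail.
    Correlations are computed on log thresholds (Pearson) and midrank-tied
    ranks (Spearman); Pearson is None when either session is constant.
    """

    n: int
    pass_pass: int
    pass_fail: int
    fail_pass: int
    fail_fail: int
    pct_agree: float
    pearson_r: float | None
    pearson_p: float | None
    spearman_rho: float | None
    spearman_p: float | None


def agreement_table(pairs: Sequence[RetestPair]) -> AgreementTable:
    """Cross-tabulate pass/fail across sessions and correlate scores."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for correlations")
    pass1 = np.array([p.score1 != NIL for p in pairs])
    pass2 = np.array([p.score2 != NIL for p in pairs])
    pp = int(np.sum(pass1 & pass2))
    pf = int(np.sum(pass1 & ~pass2))
    fp = int(np.sum(~pass1 & pass2))
    ff = int(np.sum(~pass1 & ~pass2))
    n = len(pairs)
    log1, log2 = _pair_logs(pairs)
    if np.ptp(log1) == 0 or np.ptp(log2) == 0:
        pearson_r = pearson_p = spearman_rho = spearman_p = None
    else:
        r, rp = stats.pearsonr(log1, log2)
        rho, sp = stats.spearmanr(log1, log2)
        pearson_r, pearson_p = float(r), float(rp)
        spearman_rho, spearman_p = float(rho), float(sp)
    return AgreementTable(
        n=n,
        pass_pass=pp,
        pass_fail=pf,
        fail_pass=fp,
        fail_fail=ff,
        pct_agree=100.0 * (pp + ff) / n,
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        spearman_rho=spearman_rho,
        spearman_p=spearman_p,
    )


def variance_ratio_test(
    diffs_a: Sequence[float], diffs_b: Sequence[float]
) -> tuple[float, tuple[int, int], float]:
    """Two-sided F test of var(a) = var(b).

    Returns (F, (df_a, df_b), p) with F = var(a)/var(b) on n-1 degrees of
    freedom per group.
    """
    a = np.asarray(diffs_a, dtype=float)
    b = np.asarray(diffs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    var_b = np.var(b, ddof=1)
    if var_b == 0:
        raise ValueError("zero variance in denominator group")
    F = float(np.var(a, ddof=1) / var_b)
    dfa, dfb = a.size - 1, b.size - 1
    cdf = stats.f.cdf(F, dfa, dfb)
    p = float(2.0 * min(cdf, 1.0 - cdf))
    return F, (dfa, dfb), min(p, 1.0)


def abs_diff_regression(pairs: Sequence[RetestPair]):
    """OLS of |session2 - session1| log-threshold difference on age and sex.

    Returns a statsmodels regression results object; the coefficient table
    has terms const, age_years, male.
    """
    import pandas as pd
    import statsmodels.api as sm

    log1, log2 = _pair_logs(pairs)
    y = np.abs(log2 - log1)
    age = np.array([p.age_years for p in pairs], dtype=float)
    male = np.array([1.0 if str(p.sex).upper().startswith("M") else 0.0 for p in pairs])
    if len(pairs) <= 3:
        raise ValueError("need more pairs than parameters")
    X = pd.DataFrame({"const": 1.0, "age_years": age, "male": male})
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design: age/sex/constant are not independent")
    return sm.OLS(y, X).fit()
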