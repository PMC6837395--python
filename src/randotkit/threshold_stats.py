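"""Lognormal threshold-statistic conversions and discrete score summaries.

Stereo thresholds are conventionally analysed on a log scale because
log-thresholds are approximately normal across observers.  If the common
logarithm of the threshold is normal with mean ``M`` and standard deviation
``S`` (both in log10 arcsec), the threshold itself is lognormal, and its
mean, SD, median and mode have closed forms:

    mu     = 10**M * exp(0.5 * (S ln10)**2)
    sigma  = mu * sqrt(exp((S ln10)**2) - 1)
    median = 10**M
    mode   = 10**(M - S**2 ln10)

and inversely

    M = log10(mu) - 0.5 * log10(1 + (sigma/mu)**2)
    S = sqrt(log10(1 + (sigma/mu)**2) / ln10)

These conversions make summary statistics comparable between studies that
report arcsec means and those that report log-threshold means.

The module also provides descriptive summaries of discrete Randot Preschool
score samples: percentage scoring nil, log/linear moments over the children
who obtained a threshold, and type 1 (inverse empirical CDF) percentiles
over all tested children with nil ranked worst.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._util import sample_sd
from .scores import NIL, NOT_TESTABLE, ScoreError, StereoScore, score_rank, rank_to_score

LN10 = math.log(10.0)

__all__ = [
    "LogStats",
    "LinearStats",
    "ScoreSummary",
    "log_stats_from_linear",
    "linear_stats_from_log",
    "quantile_type1",
    "summarize_scores",
    "DEFAULT_PERCENTILES",
]

#: Default percentile grid for score summaries.
DEFAULT_PERCENTILES: tuple[float, ...] = (0.25, 0.50, 0.75, 0.90, 0.95)


@dataclass(frozen=True)
class LogStats:
    """Mean and SD of log10 thresholds, in log10 arcsec."""

    M: float
    S: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.M):
            raise ValueError("M must be finite")
        if self.S < 0:
            raise ValueError("S must be >= 0")


@dataclass(frozen=True)
class LinearStats:
    """Mean, SD, median and mode of thresholds, in arcsec.

    Under the lognormal assumption mode <= median <= mean, with equality
    only in the degenerate zero-variance case.
    """

    mu: float
    sigma: float
    median: float
    mode: float


def log_stats_from_linear(mu: float, sigma: float) -> LogStats:
    """Convert an arcsec mean/SD to log-threshold mean/SD.

    Parameters
    ----------
    mu : mean threshold in arcsec, > 0.
    sigma : SD of thresholds in arcsec, >= 0.
    """
    if not mu > 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    ratio2 = (sigma / mu) ** 2
    log_term = math.log1p(ratio2) / LN10  # log10(1 + r^2), accurate for small r
    M = math.log10(mu) - 0.5 * log_term
    S = math.sqrt(log_term / LN10)
    return LogStats(M=M, S=S)


def linear_stats_from_log(M: float, S: float) -> LinearStats:
    """Convert a log-threshold mean/SD to arcsec mean, SD, median and mode."""
    if S < 0:
        raise ValueError(f"S must be >= 0, got {S}")
    w = (S * LN10) ** 2
    mu = 10.0**M * math.exp(0.5 * w)
    sigma = mu * math.sqrt(math.expm1(w))
    median = 10.0**M
    mode = 10.0 ** (M - S**2 * LN10)
    return LinearStats(mu=mu, sigma=sigma, median=median, mode=mode)


def quantile_type1(scores: Sequence[StereoScore], p: float) -> StereoScore:
    """Type 1 (inverse empirical CDF) sample quantile of discrete scores.

    Returns the ``ceil(n*p)``-th order statistic of the sample sorted under
    the score ordering 40 < 60 < ... < 800 < nil; ``Q(0)`` is the best
    observed score.  NOT_TESTABLE entries are not rankable and are rejected.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if len(scores) == 0:
        raise ValueError("empty score sample")
    if any(s == NOT_TESTABLE for s in scores):
        raise ScoreError("NOT_TESTABLE scores have no rank; exclude them first")
    ranks = sorted(score_rank(s) for s in scores)
    n = len(ranks)
    if p == 0:
        return rank_to_score(ranks[0])
    # guard against float fuzz pushing n*p just above an integer
    k = math.ceil(n * p - 1e-9)
    return rank_to_score(ranks[max(k, 1) - 1])


@dataclass(frozen=True)
class ScoreSummary:
    """Descriptive summary of a sample of Randot Preschool scores.

    Moments are computed over children who obtained a threshold (non-nil);
    percentiles over all tested children with nil ranked worst.  When every
    tested child scored nil the moments are unavailable (None) and
    ``stats_available`` is False.
    """

    n_tested: int
    pct_nil: float
    log_mean: float | None
    log_sd: float | None
    linear_mean: float | None
    linear_sd: float | None
    percentiles: Mapping[float, StereoScore] = field(default_factory=dict)

    @property
    def stats_available(self) -> bool:
        return self.log_mean is not None


def summarize_scores(
    scores: Sequence[StereoScore],
    probs: Sequence[float] = DEFAULT_PERCENTILES,
) -> ScoreSummary:
    """Summarize tested scores: nil rate, moments of non-nil scores, percentiles.

    NOT_TESTABLE entries are dropped first; the sample must be non-empty
    after that.
    """
    tested = [s for s in scores if s != NOT_TESTABLE]
    if not tested:
        raise ValueError("no tested scores in sample")
    n = len(tested)
    numeric = np.array([s for s in tested if s != NIL], dtype=float)
    pct_nil = 100.0 * (n - numeric.size) / n
    percentiles = {p: quantile_type1(tested, p) for p in probs}
    if numeric.size == 0:
        return ScoreSummary(
            n_tested=n,
            pct_nil=pct_nil,
            log_mean=None,
            log_sd=None,
            linear_mean=None,
            linear_sd=None,
            percentiles=percentiles,
        )
    logs = np.log10(numeric)
    return ScoreSummary(
        n_tested=n,
        pct_nil=pct_nil,
        log_mean=float(np.mean(logs)),
        log_sd=sample_sd(logs),
        linear_mean=float(np.mean(numeric)),
        linear_sd=sample_sd(numeric),
        percentiles=percentiles,
    )
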