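"""Randot Preschool score representation.

The test has six disparity levels (arcsec); a child who cannot pass the
easiest (800 arcsec) plate scores "nil", and a child who cannot engage with
the test at all is "not testable" (NT).  Scores are kept as plain values —
ints for the six levels plus two string sentinels — which makes them trivial
to round-trip through CSV files and pandas columns.
"""

from __future__ import annotations

import math
from typing import Union

#: The six disparity levels offered by the test, best (smallest) first.
LEVELS: tuple[int, ...] = (40, 60, 100, 200, 400, 800)

#: log10 of each level, in log10 arcsec.
LOG_LEVELS: tuple[float, ...] = tuple(math.log10(v) for v in LEVELS)

#: Failed the 800 arcsec plate (stereoblind on this test).
NIL = "nil"

#: Could not engage with the test (failed pre-test, refused glasses, ...).
NOT_TESTABLE = "NT"

#: Notional threshold assigned to a nil score in log-scale analyses:
#: one log-level above the worst available score of 800 arcsec.
NIL_NOTIONAL_ARCSEC = 1600

StereoScore = Union[int, str]

# Rank order for quantiles/correlations: better (smaller) scores first,
# nil worst.  NOT_TESTABLE has no rank.
_RANK = {level: i for i, level in enumerate(LEVELS)}
_RANK[NIL] = len(LEVELS)


class ScoreError(ValueError):
    """Raised for unknown score tokens or unrankable scores."""


def parse_score(token: object) -> StereoScore:
    """Parse a score token (CSV cell, int, float) into a canonical score.

    Accepts the six numeric levels (as int, float or string), ``nil``
    (case-insensitive) and ``NT`` / ``not testable``.
    """
    if isinstance(token, (int, float)) and not isinstance(token, bool):
        value = int(token)
        if value != token or value not in _RANK:
            raise ScoreError(
                f"invalid score level {token!r}; legal levels are {LEVELS}, "
                f"'nil' or 'NT'"
            )
        return value
    text = str(token).strip()
    low = text.lower()
    if low == "nil":
        return NIL
    if low in ("nt", "not testable", "not_testable"):
        return NOT_TESTABLE
    try:
        value = int(text)
    except ValueError:
        raise ScoreError(
            f"invalid score token {token!r}; legal levels are {LEVELS}, "
            f"'nil' or 'NT'"
        ) from None
    if value not in _RANK:
        raise ScoreError(
            f"invalid score level {value}; legal levels are {LEVELS}, "
            f"'nil' or 'NT'"
        )
    return value


def is_rankable(score: StereoScore) -> bool:
    """True for the six numeric levels and NIL; False for NOT_TESTABLE."""
    return score in _RANK


def score_rank(score: StereoScore) -> int:
    """Position of *score* in the ordering 40 < 60 < ... < 800 < nil."""
    try:
        return _RANK[score]
    except KeyError:
        raise ScoreError(f"score {score!r} has no rank") from None


def rank_to_score(rank: int) -> StereoScore:
    """Inverse of :func:`score_rank`."""
    if 0 <= rank < len(LEVELS):
        return LEVELS[rank]
    if rank == len(LEVELS):
        return NIL
    raise ScoreError(f"rank {rank} out of range")


def format_score(score: StereoScore) -> str:
    """Canonical string form used in CSV output."""
    return str(score)
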