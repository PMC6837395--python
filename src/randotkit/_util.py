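"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (table-display convention).

    Python's built-in ``round`` rounds ties to even, which disagrees with
    how percentages are conventionally printed (96.5 -> 97, not 96).
    """
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    sign = -1.0 if x < 0 else 1.0
    value = sign * math.floor(abs(x) * factor + 0.5) / factor
    return value if ndigits > 0 else float(int(value))


def sample_sd(values, ddof: int = 1) -> float:
    """Sample standard deviation; 0.0 for fewer than ddof+1 values."""
    arr = np.asarray(values, dtype=float)
    if arr.size <= ddof:
        return 0.0
    return float(np.std(arr, ddof=ddof))
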