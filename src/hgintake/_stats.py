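"""Shared descriptive-statistics helpers.

One percentile convention is used package-wide: linear interpolation
between closest ranks (numpy ``method="linear"``, Hyndman-Fan type 7).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

PERCENTILE_METHOD = "linear"


def percentile(values: Sequence[float], q: float) -> float:
    """q-th percentile (0-100), linear interpolation between closest ranks."""
    return float(np.percentile(np.asarray(values, dtype=float), q,
                               method=PERCENTILE_METHOD))


def sample_sd(values: Sequence[float]) -> float:
    """Sample (n-1) standard deviation; 0.0 for a single observation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return 0.0
    return float(np.std(arr, ddof=1))


def describe(values: Sequence[float]) -> dict[str, float]:
    """mean/median/p95/min/max summary under the package percentile rule."""
    arr = np.asarray(values, dtype=float)
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "p95": percentile(arr, 95.0),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }
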