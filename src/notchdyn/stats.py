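"""Thin statistics utilities used across the pipeline."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .exceptions import DataError

__all__ = ["mann_whitney"]


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Unpaired two-sample Mann-Whitney U test; returns (U, p)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
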