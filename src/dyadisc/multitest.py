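"""Multiple-comparison corrections.

Thin, validated wrappers around ``statsmodels.stats.multitest``: Holm-
Bonferroni step-down control of the family-wise error rate (used across
brain regions) and Benjamini-Hochberg step-up FDR control (used across the
behavioral contrast family).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests


def _validated(p_values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p_values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (clipped at 1, monotone)."""
    arr = _validated(p_values)
    return multipletests(arr, method="holm")[1]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted p-values."""
    arr = _validated(p_values)
    return multipletests(arr, method="fdr_bh")[1]
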