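"""Multiple-testing correction (Benjamini–Hochberg, Holm, Bonferroni)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

_METHODS = {
    "bh": "fdr_bh",
    "fdr_bh": "fdr_bh",
    "holm": "holm",
    "bonferroni": "bonferroni",
}


def multiple_correction(pvalues, method: str = "bh") -> np.ndarray:
    """Adjusted p-values, same order as the input.

    ``method`` is one of ``bh`` (Benjamini–Hochberg step-up), ``holm``,
    or ``bonferroni``.  An empty input yields an empty output.
    """
    key = _METHODS.get(method.lower())
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=key)[1]
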