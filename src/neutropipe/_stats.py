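"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p value.

    Exact null distribution when both groups have <= 25 observations and the
    data are tie-free; otherwise the normal approximation with tie and
    continuity correction. Completely tied data give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 25 and b.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))
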