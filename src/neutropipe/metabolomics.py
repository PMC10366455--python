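"""Metabolite-level group comparison.

Per metabolite: a Box-Cox transform (lambda by maximum profile
log-likelihood on the pooled values), a two-sided Student's t test with
pooled variance on the transformed values, a Hedges' g standardized effect
size (positive = higher in the case group), and Benjamini-Hochberg
adjustment across metabolites. The intensity matrix is assumed already
normalized upstream (e.g. to internal standards).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diffexpr import benjamini_hochberg
from .io import SampleTable

logger = logging.getLogger(__name__)

LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.05), 10)


def box_cox(values: np.ndarray, lambda_grid: np.ndarray = LAMBDA_GRID,
            forced_lambda: float | None = None) -> tuple[np.ndarray, float]:
    """Box-Cox transform with lambda chosen by maximum profile log-likelihood.

    Nonpositive inputs are shifted to ``min + eps`` before transforming (the
    shift only affects location, not the chosen family member's
    monotonicity). Constant input returns the identity with lambda = 1 and a
    warning. ``y = (x^lambda - 1) / lambda`` and ``y = ln x`` at lambda = 0.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values must be removed before Box-Cox")
    if np.all(x == x[0]):
        logger.warning("constant input: Box-Cox lambda undefined, identity returned")
        return x.copy(), 1.0
    if x.min() <= 0:
        shift = -x.min() + 1e-6 * max(np.ptp(x), 1.0)
        logger.info("shifting nonpositive values by %.6g before Box-Cox", shift)
        x = x + shift
    if forced_lambda is not None:
        lam = float(forced_lambda)
    else:
        lls = np.array([sps.boxcox_llf(l, x) for l in lambda_grid])
        lam = float(lambda_grid[int(np.argmax(lls))])
    if lam == 0.0:
        return np.log(x), lam
    return (x ** lam - 1.0) / lam, lam


def hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    """Bias-corrected standardized mean difference, b relative to a.

    g = J * (mean_b - mean_a) / s_pooled with the pooled (df-weighted)
    standard deviation and small-sample correction
    J = 1 - 3 / (4 (n_a + n_b) - 9).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("pooled SD is zero; effect size undefined")
    d = (b.mean() - a.mean()) / np.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(J * d)


def metabolite_panel(matrix: pd.DataFrame, samples: SampleTable,
                     contrast: tuple[str, str] = ("cap_admission", "control"),
                     transform: str = "boxcox", welch: bool = False) -> pd.DataFrame:
    """Effect-size table over a metabolite-by-sample intensity matrix.

    Parameters
    ----------
    contrast : (case, reference); g > 0 means higher in the case group.
    transform : "boxcox" (default) or "raw" — scale on which t and g are
        computed.

    Metabolites with fewer than 2 non-missing values in either group are
    skipped with a log entry.
    """
    case, ref = contrast
    samples.require_samples(matrix.columns)
    case_ids = [s for s in matrix.columns if samples.group_of(s) == case]
    ref_ids = [s for s in matrix.columns if samples.group_of(s) == ref]
    rows = []
    for met in matrix.index:
        a = matrix.loc[met, ref_ids].dropna().to_numpy(dtype=float)
        b = matrix.loc[met, case_ids].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            logger.info("metabolite %s skipped: <2 values in a group", met)
            continue
        if transform == "boxcox":
            pooled, lam = box_cox(np.concatenate([a, b]))
            ta, tb = pooled[: a.size], pooled[a.size:]
        elif transform == "raw":
            ta, tb, lam = a, b, np.nan
        else:
            raise ValueError(f"unknown transform {transform!r}")
        t_res = sps.ttest_ind(tb, ta, equal_var=not welch)
        rows.append({
            "metabolite": met,
            "hedges_g": hedges_g(ta, tb),
            "t_stat": float(t_res.statistic),
            "p_value": float(t_res.pvalue),
            "lambda": lam,
            "n_control": int(a.size),
            "n_case": int(b.size),
        })
    out = pd.DataFrame(rows, columns=["metabolite", "hedges_g", "t_stat", "p_value",
                                      "lambda", "n_control", "n_case"])
    out["bh_adjusted_p"] = (benjamini_hochberg(out["p_value"].to_numpy())
                            if len(out) else np.array([]))
    return out
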