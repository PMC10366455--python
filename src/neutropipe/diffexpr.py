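"""Normalization and negative-binomial differential expression.

The stage mirrors the standard bulk RNA-seq workflow at desk scale:
median-of-ratios size factors, a per-gene NB log-linear model
``log mu = log s_j + b0 + b1 * group`` fitted by iteratively reweighted
least squares, gene-wise dispersion by Cox-Reid adjusted profile likelihood
shrunk 50/50 (log scale) toward a fitted mean-dispersion trend
``a / mu + phi0``, a Wald test on the group coefficient and
Benjamini-Hochberg adjustment across tested genes.

Empirical-Bayes fold-change shrinkage, outlier count filtering and
independent filtering are intentionally not part of this stage; it aims to
be a sound, transparent NB Wald test rather than a re-implementation of any
particular tool's internals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import t as t_dist

from .io import CountMatrix, SampleTable

logger = logging.getLogger(__name__)

DISPERSION_MIN = 1e-8
DISPERSION_MAX = 10.0
MIN_NONZERO = 3  # genes with fewer nonzero counts are not testable


def size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over genes (restricted to
    genes with a positive geometric mean across samples) of
    ``count_gj / geometric_mean_g``.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    with np.errstate(divide="ignore"):
        logc = np.log(mat)
    usable = np.all(np.isfinite(logc), axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; filter samples or genes first"
        )
    log_geomean = logc[usable].mean(axis=1)
    ratios = np.exp(logc[usable] - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    if np.any(factors <= 0):
        raise ValueError("non-positive size factor; input too sparse")
    return factors


def log_norm_expression(counts: CountMatrix) -> pd.DataFrame:
    """log2(median-of-ratios-normalized count + 1), as a genes-x-samples frame.

    This is the expression scale consumed by pathway scoring, the
    co-expression network and trajectory clustering.
    """
    sf = size_factors(counts)
    vals = np.log2(counts.counts / sf[None, :] + 1.0)
    return pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)


def benjamini_hochberg(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values.

    NaN entries (untested hypotheses) are passed through as NaN and excluded
    from the number of tests ``m`` unless ``m`` is given explicitly.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p values must lie in [0, 1]")
    k = pv.size
    if k == 0:
        return out
    m_eff = k if m is None else int(m)
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m_eff / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(k)
    res[order] = adj
    out[mask] = res
    return out


def _nb_irls(y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
             max_iter: int = 50, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NB IRLS for a shared two-column design across genes.

    y : (G, n) counts, x : (n,) 0/1 group indicator, offset : (n,) log size
    factors, alpha : (G,) dispersions. Returns (beta (G,2), se1 (G,),
    converged (G,)). Uses the log link; W = mu / (1 + alpha * mu).
    """
    G, n = y.shape
    ones = np.ones(n)
    # moment start: group means on the offset-corrected scale
    sf = np.exp(offset)
    m0 = (y[:, x == 0] / sf[x == 0]).mean(axis=1)
    m1 = (y[:, x == 1] / sf[x == 1]).mean(axis=1)
    m0 = np.maximum(m0, 1e-8)
    m1 = np.maximum(m1, 1e-8)
    beta = np.column_stack([np.log(m0), np.log(m1) - np.log(m0)])
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        eta = offset[None, :] + beta[:, [0]] + beta[:, [1]] * x[None, :]
        eta = np.clip(eta, -50, 50)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        # normal equations for X = [1, x]
        s00 = w @ ones
        s01 = w @ x
        s11 = w @ (x * x)
        t0 = (w * z) @ ones
        t1 = (w * z) @ x
        det = s00 * s11 - s01 * s01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        b0 = (s11 * t0 - s01 * t1) / det
        b1 = (s00 * t1 - s01 * t0) / det
        new = np.column_stack([b0, b1])
        step = np.abs(new - beta).max(axis=1)
        beta = new
        newly = step < tol
        converged |= newly
        if converged.all():
            break
    eta = offset[None, :] + beta[:, [0]] + beta[:, [1]] * x[None, :]
    mu = np.exp(np.clip(eta, -50, 50))
    w = mu / (1.0 + alpha[:, None] * mu)
    s00 = w @ ones
    s01 = w @ x
    s11 = w @ (x * x)
    det = np.maximum(s00 * s11 - s01 * s01, 1e-300)
    se1 = np.sqrt(s00 / det)
    return beta, se1, converged


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood; y, mu are (G, n), alpha broadcastable to (G, 1)."""
    r = 1.0 / alpha
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu) + 1e-300)
    ).sum(axis=1)


def _dispersion_mle(y: np.ndarray, mu: np.ndarray, x: np.ndarray,
                    grid_size: int = 41) -> np.ndarray:
    """Cox-Reid adjusted profile-likelihood dispersion on a log-spaced grid.

    The adjustment subtracts 0.5 * log det(X'WX), which removes most of the
    downward bias of plain MLE dispersion when the mean uses 2 fitted
    parameters.
    """
    G, n = y.shape
    grid = np.exp(np.linspace(np.log(1e-4), np.log(DISPERSION_MAX), grid_size))
    ll = np.empty((G, grid_size))
    ones = np.ones(n)
    for k, a in enumerate(grid):
        alpha_k = np.full((G, 1), a)
        llk = _nb_loglik(y, mu, alpha_k)
        w = mu / (1.0 + a * mu)
        s00 = w @ ones
        s01 = w @ x
        s11 = w @ (x * x)
        det = np.maximum(s00 * s11 - s01 * s01, 1e-300)
        ll[:, k] = llk - 0.5 * np.log(det)
    best = np.argmax(ll, axis=1)
    return grid[best]


def _fit_dispersion_trend(alpha_mle: np.ndarray, base_mean: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a / mean + phi0 over moderately expressed genes."""
    mask = (base_mean > 1) & (alpha_mle > 1e-4) & (alpha_mle < DISPERSION_MAX * 0.99)
    if mask.sum() < 10:
        mask = np.ones_like(base_mean, dtype=bool)
    xm = 1.0 / base_mean[mask]
    ym = alpha_mle[mask]
    A = np.column_stack([xm, np.ones(xm.size)])
    coef, *_ = np.linalg.lstsq(A, ym, rcond=None)
    a = max(coef[0], 0.0)
    phi0 = max(coef[1], 1e-6)
    return float(a), float(phi0)


def fit_de(counts: CountMatrix, samples: SampleTable,
           groups: tuple[str, str] = ("cap_admission", "control"),
           min_nonzero: int = MIN_NONZERO) -> pd.DataFrame:
    """Two-group NB Wald differential expression.

    Parameters
    ----------
    groups : (case, reference) pair of group labels; the reported
        ``log2_fold_change`` is case over reference.

    Returns
    -------
    DataFrame with columns gene_id, base_mean, log2_fold_change, wald_stat,
    p_value, bh_adjusted_p, converged. Genes failing the expression filter
    or IRLS convergence carry NaN p values and are excluded from the BH
    denominator.
    """
    case, ref = groups
    samples.require_samples(counts.sample_ids)
    case_ids = [s for s in counts.sample_ids if samples.group_of(s) == case]
    ref_ids = [s for s in counts.sample_ids if samples.group_of(s) == ref]
    if len(case_ids) < 2 or len(ref_ids) < 2:
        raise ValueError("both groups need at least 2 samples")
    sub = counts.subset_samples(ref_ids + case_ids)
    x = np.array([0] * len(ref_ids) + [1] * len(case_ids), dtype=float)
    y = sub.counts.astype(float)

    sf = size_factors(sub)
    offset = np.log(sf)
    norm_counts = y / sf[None, :]
    base_mean = norm_counts.mean(axis=1)

    testable = (y > 0).sum(axis=1) >= min_nonzero
    n_skipped = int((~testable).sum())
    if n_skipped:
        logger.info("excluding %d genes with < %d nonzero counts", n_skipped, min_nonzero)
    yt = y[testable]
    bm = base_mean[testable]

    # pass 1: fit means with a rough common dispersion, then estimate per-gene
    alpha0 = np.full(yt.shape[0], 0.1)
    beta, _se, _conv = _nb_irls(yt, x, offset, alpha0)
    eta = offset[None, :] + beta[:, [0]] + beta[:, [1]] * x[None, :]
    mu = np.exp(np.clip(eta, -50, 50))
    alpha_mle = _dispersion_mle(yt, mu, x)
    a_tr, phi0_tr = _fit_dispersion_trend(alpha_mle, bm)
    alpha_trend = np.clip(a_tr / np.maximum(bm, 1e-8) + phi0_tr, DISPERSION_MIN, DISPERSION_MAX)
    alpha = np.exp(0.5 * (np.log(np.clip(alpha_mle, DISPERSION_MIN, DISPERSION_MAX))
                          + np.log(alpha_trend)))
    alpha = np.clip(alpha, DISPERSION_MIN, DISPERSION_MAX)

    # pass 2: final fit and Wald test; t reference with n - 2 df keeps the
    # test honest in small cohorts (coincides with the normal at large n)
    beta, se1, conv = _nb_irls(yt, x, offset, alpha)
    wald = beta[:, 1] / se1
    pval = 2.0 * t_dist.sf(np.abs(wald), df=max(x.size - 2, 1))
    pval[~conv] = np.nan
    if (~conv).any():
        logger.warning("%d genes did not converge; excluded from testing", int((~conv).sum()))

    out = pd.DataFrame({
        "gene_id": counts.gene_ids,
        "base_mean": base_mean,
        "log2_fold_change": np.nan,
        "wald_stat": np.nan,
        "p_value": np.nan,
        "bh_adjusted_p": np.nan,
        "converged": False,
    })
    idx = np.flatnonzero(testable)
    out.loc[idx, "log2_fold_change"] = beta[:, 1] / np.log(2.0)
    out.loc[idx, "wald_stat"] = wald
    out.loc[idx, "p_value"] = pval
    out.loc[idx, "converged"] = conv
    out["bh_adjusted_p"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out
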