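"""Per-sample pathway activity scores.

Each gene's normalized log expression is squashed to (-1, 1) by a shifted
logistic map

    f(x) = 2 / (1 + exp(-beta * (x - center))) - 1  ==  tanh(beta * (x - center) / 2)

whose steepness ``beta`` is the absolute slope of a univariate weighted
logistic regression of the sample group (case vs control) on the gene's
standardized expression, and whose ``center`` is the weighted mean
expression of the fitting samples. A pathway's score in a sample is the
mean of the squashed values over the pathway's measured genes, so scores
live in [-1, 1]: 0 means "at the fitting cohort's center", positive means
expression above it, weighted toward genes that discriminate the groups.

The regression is fit on one contrast (by default admission vs control);
other samples (e.g. recovery) are scaled with those frozen coefficients,
never refit. Class-balance weights (inverse class frequency) are the
default because the cohort is imbalanced; separable genes are kept finite
by a small ridge penalty and a cap on the standardized slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import wilcoxon_rank_sum
from .diffexpr import benjamini_hochberg
from .io import GeneSetCollection, SampleTable

logger = logging.getLogger(__name__)

RIDGE = 1e-4
BETA_CAP = 25.0  # cap on the standardized slope for separable genes


@dataclass
class GeneScaling:
    """Logistic squashing coefficients for one gene.

    ``beta`` is expressed per unit of the (log) expression scale used for
    fitting; ``center`` is the location on that same scale.
    """

    gene_id: str
    beta: float
    center: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")
        if not np.isfinite(self.center):
            raise ValueError("center must be finite")


def _class_weights(labels: np.ndarray, mode: str) -> np.ndarray:
    n = labels.size
    if mode == "uniform":
        return np.ones(n)
    if mode == "balanced":
        n1 = labels.sum()
        n0 = n - n1
        w = np.where(labels == 1, n / (2.0 * n1), n / (2.0 * n0))
        return w
    raise ValueError(f"unknown weights_mode {mode!r}")


def _logistic_irls(z: np.ndarray, y: np.ndarray, w: np.ndarray,
                   ridge: float = RIDGE, cap: float = BETA_CAP,
                   max_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Ridge-penalized weighted logistic IRLS, vectorized across genes.

    z : (G, n) standardized predictors, y : (n,) 0/1 labels, w : (n,)
    observation weights. The penalty applies to the slope only. Returns the
    slope per gene, clipped to [-cap, cap].
    """
    z = np.atleast_2d(z)
    G, n = z.shape
    b0 = np.zeros(G)
    b1 = np.zeros(G)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * z, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        wr = w[None, :] * p * (1.0 - p)
        wr = np.maximum(wr, 1e-12)
        resp = eta + (y[None, :] - p) / (p * (1.0 - p) + 1e-12)
        s00 = wr.sum(axis=1)
        s01 = (wr * z).sum(axis=1)
        s11 = (wr * z * z).sum(axis=1) + ridge
        t0 = (wr * resp).sum(axis=1)
        t1 = (wr * resp * z).sum(axis=1)
        det = np.maximum(s00 * s11 - s01 * s01, 1e-300)
        nb0 = (s11 * t0 - s01 * t1) / det
        nb1 = (s00 * t1 - s01 * t0) / det
        nb1 = np.clip(nb1, -1.5 * cap, 1.5 * cap)
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        if np.all(step < tol):
            break
    return np.clip(b1, -cap, cap)


def fit_gene_scaling(expr: np.ndarray, labels: np.ndarray,
                     weights_mode: str = "balanced",
                     gene_id: str = "gene") -> GeneScaling:
    """Fit the squashing coefficients for a single gene.

    Parameters
    ----------
    expr : normalized log-expression over the fitting samples
    labels : 0/1 group labels (1 = case); both classes must be present
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(expr)):
        raise ValueError("expression must be finite")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (labels == classes.max()).astype(float)
    w = _class_weights(y, weights_mode)
    center = float(np.average(expr, weights=w))
    sd = float(np.sqrt(np.average((expr - center) ** 2, weights=w)))
    if sd == 0.0:
        return GeneScaling(gene_id, 0.0, center)
    z = (expr - center) / sd
    slope = _logistic_irls(z[None, :], y, w)[0]
    return GeneScaling(gene_id, abs(float(slope)) / sd, center)


def fit_scalings(expr: pd.DataFrame, samples: SampleTable,
                 contrast: tuple[str, str] = ("cap_admission", "control"),
                 weights_mode: str = "balanced") -> pd.DataFrame:
    """Fit squashing coefficients for every gene on one two-group contrast.

    ``expr`` is a genes-x-samples frame of normalized log expression; only
    samples belonging to the contrast groups are used for fitting. Returns a
    frame with columns gene_id, beta, center.
    """
    case, ref = contrast
    samples.require_samples(expr.columns)
    fit_ids = [s for s in expr.columns if samples.group_of(s) in (case, ref)]
    if not fit_ids:
        raise ValueError("no fitting samples for the requested contrast")
    labels = np.array([1.0 if samples.group_of(s) == case else 0.0 for s in fit_ids])
    if labels.min() == labels.max():
        raise ValueError("contrast requires both groups present")
    X = expr[fit_ids].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("expression must be finite")
    w = _class_weights(labels, weights_mode)
    centers = np.average(X, axis=1, weights=w)
    sds = np.sqrt(np.average((X - centers[:, None]) ** 2, axis=1, weights=w))
    ok = sds > 0
    betas = np.zeros(X.shape[0])
    if ok.any():
        Z = (X[ok] - centers[ok, None]) / sds[ok, None]
        slopes = _logistic_irls(Z, labels, w)
        betas[ok] = np.abs(slopes) / sds[ok]
    return pd.DataFrame({"gene_id": list(expr.index), "beta": betas, "center": centers})


def scale_expression(x, s: GeneScaling):
    """Squash expression to (-1, 1): ``2 / (1 + exp(-beta (x - center))) - 1``."""
    return np.tanh(s.beta * (np.asarray(x, dtype=float) - s.center) / 2.0)


def scale_matrix(expr: pd.DataFrame, scalings: pd.DataFrame) -> pd.DataFrame:
    """Apply the per-gene squashing to a genes-x-samples expression frame."""
    sc = scalings.set_index("gene_id")
    missing = [g for g in expr.index if g not in sc.index]
    if missing:
        raise ValueError(f"no scaling fitted for genes: {missing[:10]}")
    beta = sc.loc[expr.index, "beta"].to_numpy()
    center = sc.loc[expr.index, "center"].to_numpy()
    vals = np.tanh(beta[:, None] * (expr.to_numpy(dtype=float) - center[:, None]) / 2.0)
    return pd.DataFrame(vals, index=expr.index, columns=expr.columns)


@dataclass
class PathwayScoreMatrix:
    """Pathway-by-sample score matrix with per-pathway gene usage counts."""

    scores: pd.DataFrame          # pathways x samples, values in [-1, 1]
    n_genes_used: pd.Series       # pathway -> number of measured genes averaged

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if np.any(np.abs(vals) > 1.0 + 1e-12):
            raise ValueError("pathway scores must lie in [-1, 1]")


def pathway_scores(expr: pd.DataFrame, scalings: pd.DataFrame,
                   sets: GeneSetCollection) -> PathwayScoreMatrix:
    """Mean squashed expression over each pathway's measured genes.

    Pathway genes absent from ``expr`` are dropped; pathways with no
    measured genes are omitted with a warning. Raises if no pathway has any
    measured gene.
    """
    scaled = scale_matrix(expr, scalings)
    measured = sets.intersect(expr.index)
    if len(measured) == 0:
        raise ValueError("no gene set overlaps the measured genes")
    rows = {}
    n_used = {}
    for name in measured.names():
        genes = measured.genes(name)
        rows[name] = scaled.loc[genes].mean(axis=0)
        n_used[name] = len(genes)
    scores = pd.DataFrame(rows).T
    scores.columns = expr.columns
    return PathwayScoreMatrix(scores, pd.Series(n_used, name="n_genes_used"))


def score_group_test(scores: PathwayScoreMatrix | pd.DataFrame, samples: SampleTable,
                     groups: tuple[str, str] = ("cap_admission", "control")) -> pd.DataFrame:
    """Per-pathway two-sided Wilcoxon rank-sum between two groups, with BH."""
    mat = scores.scores if isinstance(scores, PathwayScoreMatrix) else scores
    samples.require_samples(mat.columns)
    a_ids = [s for s in mat.columns if samples.group_of(s) == groups[0]]
    b_ids = [s for s in mat.columns if samples.group_of(s) == groups[1]]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("both groups need at least 2 samples")
    recs = []
    for pw in mat.index:
        a = mat.loc[pw, a_ids].to_numpy(dtype=float)
        b = mat.loc[pw, b_ids].to_numpy(dtype=float)
        recs.append({
            "pathway": pw,
            "median_diff": float(np.median(a) - np.median(b)),
            "p_value": wilcoxon_rank_sum(a, b),
        })
    out = pd.DataFrame(recs)
    out["bh_adjusted_p"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out
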