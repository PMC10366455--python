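"""Phenotype integration: stimulation deltas and Spearman correlation matrices.

Ex vivo degranulation is summarized per sample as the stimulated MPO
release minus the vehicle (unstimulated) value. Associations between
pathway scores, MPO deltas and plasma biomarkers are quantified with
Spearman's rho on pairwise-complete observations, optionally stratified by
sample group; p values come from the exact permutation distribution for
n <= 10 pairs and from the t approximation (midrank ties) otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SampleTable

logger = logging.getLogger(__name__)


def stimulation_delta(stim: pd.DataFrame) -> pd.DataFrame:
    """Per-sample stimulated-minus-vehicle MPO deltas.

    Input is the long stimulation table (sample_id, condition, mpo).
    Returns a frame indexed by sample_id with columns delta_lps and
    delta_kpneu; samples without a vehicle measurement are excluded with a
    log entry, and a missing stimulated value leaves only that delta NaN.
    """
    if stim.duplicated(subset=["sample_id", "condition"]).any():
        raise ValueError("duplicate (sample, condition) rows in stimulation table")
    wide = stim.pivot(index="sample_id", columns="condition", values="mpo")
    for cond in ("vehicle", "lps", "kpneu"):
        if cond not in wide.columns:
            wide[cond] = np.nan
    no_vehicle = wide.index[wide["vehicle"].isna()]
    for s in no_vehicle:
        logger.info("sample %s has no vehicle measurement; excluded from deltas", s)
    wide = wide.drop(index=no_vehicle)
    out = pd.DataFrame({
        "delta_lps": wide["lps"] - wide["vehicle"],
        "delta_kpneu": wide["kpneu"] - wide["vehicle"],
    })
    out.index.name = "sample_id"
    return out


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float,
                      chunk: int = 100_000) -> float:
    """Two-sided exact permutation p for Spearman rho on ranked data."""
    n = rx.size
    total = math.factorial(n)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.linalg.norm(rxc) * np.linalg.norm(ryc)
    count = 0
    perm_iter = itertools.permutations(ryc)
    target = abs(rho) - 1e-12
    while True:
        block = np.array(list(itertools.islice(perm_iter, chunk)))
        if block.size == 0:
            break
        rhos = (block @ rxc) / denom
        count += int(np.sum(np.abs(rhos) >= target))
    return count / total


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> tuple[float, float, int]:
    """Spearman correlation with pairwise-complete observations.

    Returns (rho, p, n). Ties are midranked. For n <= ``exact_max_n`` the p
    value is the exact two-sided permutation probability; otherwise the
    t approximation. Zero variance in either ranked vector yields
    (nan, nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    xv, yv = x[mask], y[mask]
    n = int(xv.size)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    rx = sps.rankdata(xv)
    ry = sps.rankdata(yv)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        logger.warning("zero variance after ranking; Spearman undefined")
        return float("nan"), float("nan"), n
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0), n


def correlation_matrix(variables: pd.DataFrame, strata: pd.Series | None = None,
                       min_n: int = 3) -> dict[str, dict[str, pd.DataFrame]]:
    """Pairwise-complete Spearman correlation matrices, optionally per stratum.

    ``variables`` is samples x variables. Returns a mapping
    stratum -> {"rho", "p", "n"} of square DataFrames; the unstratified
    result lives under the key "all". Strata with fewer than ``min_n``
    samples are omitted with a warning.
    """
    cols = list(variables.columns)
    groups: dict[str, pd.DataFrame] = {"all": variables}
    if strata is not None:
        strata = strata.loc[variables.index]
        for s in strata.dropna().unique():
            groups[str(s)] = variables.loc[strata == s]
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for name, sub in groups.items():
        if len(sub) < min_n:
            logger.warning("stratum %s has < %d samples; omitted", name, min_n)
            continue
        k = len(cols)
        rho = np.eye(k)
        pmat = np.zeros((k, k))
        nmat = np.full((k, k), len(sub))
        for i in range(k):
            nmat[i, i] = int(sub[cols[i]].notna().sum())
            for j in range(i + 1, k):
                xi = sub[cols[i]].to_numpy(dtype=float)
                yj = sub[cols[j]].to_numpy(dtype=float)
                pairs = int((~(np.isnan(xi) | np.isnan(yj))).sum())
                if pairs < min_n:
                    r, p, n = float("nan"), float("nan"), pairs
                else:
                    r, p, n = spearman(xi, yj)
                rho[i, j] = rho[j, i] = r
                pmat[i, j] = pmat[j, i] = p
                nmat[i, j] = nmat[j, i] = n
        out[name] = {
            "rho": pd.DataFrame(rho, index=cols, columns=cols),
            "p": pd.DataFrame(pmat, index=cols, columns=cols),
            "n": pd.DataFrame(nmat, index=cols, columns=cols),
        }
    return out


def correlation_long(matrices: dict[str, dict[str, pd.DataFrame]]) -> pd.DataFrame:
    """Flatten correlation matrices to long format (var1, var2, stratum, rho, p, n)."""
    rows = []
    for stratum, mats in matrices.items():
        cols = list(mats["rho"].columns)
        for i, v1 in enumerate(cols):
            for v2 in cols[i + 1:]:
                rows.append({
                    "var1": v1, "var2": v2, "stratum": stratum,
                    "rho": mats["rho"].loc[v1, v2],
                    "p": mats["p"].loc[v1, v2],
                    "n": mats["n"].loc[v1, v2],
                })
    return pd.DataFrame(rows, columns=["var1", "var2", "stratum", "rho", "p", "n"])


def pathway_phenotype_table(scores: pd.DataFrame, phenotypes: pd.DataFrame,
                            samples: SampleTable | None = None,
                            group: str | None = None) -> pd.DataFrame:
    """Correlate each pathway score with each phenotype column.

    ``scores`` is pathways x samples, ``phenotypes`` samples x variables.
    Optionally restrict to one sample group first. Returns a long frame
    (pathway, phenotype, rho, p, n).
    """
    common = [s for s in scores.columns if s in phenotypes.index]
    if group is not None:
        if samples is None:
            raise ValueError("samples table required to filter by group")
        common = [s for s in common if samples.group_of(s) == group]
    if len(common) < 3:
        raise ValueError("fewer than 3 samples shared between scores and phenotypes")
    rows = []
    for pw in scores.index:
        for var in phenotypes.columns:
            x = scores.loc[pw, common].to_numpy(dtype=float)
            y = phenotypes.loc[common, var].to_numpy(dtype=float)
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3:
                continue
            r, p, n = spearman(x, y)
            rows.append({"pathway": pw, "phenotype": var, "rho": r, "p": p, "n": n})
    return pd.DataFrame(rows, columns=["pathway", "phenotype", "rho", "p", "n"])
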