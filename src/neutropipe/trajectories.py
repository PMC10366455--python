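"""Trajectory clustering of differential genes across ordered groups.

Admission-significant genes are summarized as a 3-point profile — the mean
z-scored log expression per group in the order control, admission,
recovery — and clustered by the shape of that profile: average linkage on
1 - Pearson correlation between profiles, with the cluster count chosen by
maximum mean silhouette over a scanned range. Clusters smaller than
``min_genes`` are dissolved into an "unclustered" bin. Labels are
deterministic, ordered by decreasing cluster size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .io import GROUPS, SampleTable

logger = logging.getLogger(__name__)

UNCLUSTERED = "unclustered"


@dataclass
class TrajectoryClustering:
    labels: pd.Series                 # gene -> cluster label ("1", "2", ... or "unclustered")
    profiles: pd.DataFrame            # cluster -> mean standardized profile over groups
    sizes: pd.Series
    silhouette_by_k: pd.Series
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.labels.index, "cluster": self.labels.to_numpy()})


def _group_profiles(expr: pd.DataFrame, samples: SampleTable) -> pd.DataFrame:
    """Per-gene mean of z-scored expression within each ordered group."""
    samples.require_samples(expr.columns)
    X = expr.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    zdf = pd.DataFrame(Z, index=expr.index, columns=expr.columns)
    cols = {}
    for g in GROUPS:
        ids = [s for s in expr.columns if samples.group_of(s) == g]
        if not ids:
            raise ValueError(f"group {g!r} has no samples in the expression matrix")
        cols[g] = zdf[ids].mean(axis=1)
    return pd.DataFrame(cols)[list(GROUPS)]


def cluster_trajectories(expr: pd.DataFrame, samples: SampleTable, deg_list: list[str],
                         k_range: range = range(2, 9), min_genes: int = 15,
                         min_silhouette: float = 0.25,
                         parsimony_margin: float = 0.1,
                         merge_cor: float = 0.9) -> TrajectoryClustering:
    """Cluster differential genes by the shape of their group-mean trajectory.

    The cluster count is the smallest k whose mean silhouette comes within
    ``parsimony_margin`` of the best over ``k_range`` — silhouette alone is
    scale-invariant and rewards splitting even a single noisy blob, so ties
    within the margin go to the simplest solution. If no k reaches
    ``min_silhouette`` the genes form a single trajectory group. Clusters
    whose mean profiles correlate above ``merge_cor`` describe the same
    trend and are merged before small clusters are dissolved.
    """
    degs = [g for g in deg_list if g in expr.index]
    if len(degs) < 2:
        raise ValueError("need at least 2 differential genes present in the expression matrix")
    prof = _group_profiles(expr.loc[degs], samples)
    P = prof.to_numpy(dtype=float)
    # correlation distance between 3-point profiles
    Pc = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Pc, axis=1)
    norms[norms == 0] = 1.0
    C = np.clip((Pc / norms[:, None]) @ (Pc / norms[:, None]).T, -1.0, 1.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))

    sil = {}
    labelings = {}
    for k in k_range:
        if k >= len(degs):
            continue
        lab = fcluster(Z, t=k, criterion="maxclust")
        if np.unique(lab).size < 2:
            continue
        sil[k] = float(silhouette_score(D, lab, metric="precomputed"))
        labelings[k] = lab
    if not sil or max(sil.values()) < min_silhouette:
        chosen_k = 1
        lab = np.ones(len(degs), dtype=int)
    else:
        best = max(sil.values())
        chosen_k = min(k for k, s in sil.items() if s >= best - parsimony_margin)
        lab = labelings[chosen_k]

    # merge clusters that describe the same trend
    changed = True
    while changed and np.unique(lab).size > 1:
        changed = False
        ids = list(np.unique(lab))
        means = {c: P[lab == c].mean(axis=0) for c in ids}
        for i, c1 in enumerate(ids):
            for c2 in ids[i + 1:]:
                m1, m2 = means[c1], means[c2]
                if m1.std() == 0 or m2.std() == 0:
                    continue
                if np.corrcoef(m1, m2)[0, 1] > merge_cor:
                    lab[lab == c2] = c1
                    changed = True
                    break
            if changed:
                break

    # dissolve small clusters, relabel by decreasing size
    counts = pd.Series(lab).value_counts()
    keep = [c for c in counts.index if counts[c] >= min_genes]
    keep.sort(key=lambda c: (-counts[c], c))
    mapping = {c: str(i + 1) for i, c in enumerate(keep)}
    labels = pd.Series(
        [mapping.get(c, UNCLUSTERED) for c in lab], index=degs, dtype=object)
    profiles = {}
    for name in sorted(set(mapping.values()), key=int):
        genes = labels.index[labels == name]
        profiles[name] = prof.loc[genes].mean(axis=0)
    prof_df = pd.DataFrame(profiles).T if profiles else pd.DataFrame(columns=list(GROUPS))
    sizes = labels.value_counts()
    return TrajectoryClustering(
        labels=labels,
        profiles=prof_df,
        sizes=sizes,
        silhouette_by_k=pd.Series(sil, dtype=float).sort_index(),
        chosen_k=chosen_k,
    )
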