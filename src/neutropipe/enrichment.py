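"""Gene-set enrichment: preranked GSEA and hypergeometric over-representation.

``gsea_preranked`` implements the classic weighted Kolmogorov-Smirnov-style
enrichment score on a signed gene ranking (hit steps proportional to
|stat|^w, miss steps 1/(N-K)) with a gene-permutation null: for each set
size, random same-size gene sets drawn from the ranked universe. The
two-sided permutation p carries a +1 pseudocount, so the smallest
attainable p is 1/(n_perm + 1). Adaptive p refinement of the kind some
preranked tools perform is deliberately not reproduced; a plain
permutation null is transparent and adequate at the scales this package
targets.

``hypergeom_ora`` is the standard upper-tail hypergeometric
over-representation test of a query gene list against a set within a
measured universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import benjamini_hochberg
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


def _order_ranking(ranking: pd.Series) -> pd.Series:
    """Sort descending by statistic, ties broken by gene ID (lexicographic)."""
    df = pd.DataFrame({"gene": ranking.index.astype(str), "stat": ranking.to_numpy(dtype=float)})
    if df["gene"].duplicated().any():
        raise ValueError("ranking contains duplicate gene IDs")
    if df["stat"].isna().any():
        df = df.dropna(subset=["stat"])
    df = df.sort_values(["stat", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(df["stat"].to_numpy(), index=df["gene"].to_numpy())


def _es_from_positions(pos: np.ndarray, absstat: np.ndarray, n: int,
                       weight: float) -> tuple[float, int]:
    """Enrichment score from sorted 0-based hit positions.

    Returns (es, extremum position index into ``pos``; negative index
    encodes 'just before hit'). The running sum between hits decays
    linearly, so its extrema occur at hit positions (after the hit step)
    or immediately before a hit.
    """
    k = pos.size
    if weight == 0:
        hit_w = np.full(k, 1.0 / k)
    else:
        a = np.abs(absstat[pos]) ** weight
        tot = a.sum()
        if tot == 0:
            hit_w = np.full(k, 1.0 / k)
        else:
            hit_w = a / tot
    miss = 1.0 / (n - k)
    cum_hit = np.cumsum(hit_w)
    miss_before = (pos - np.arange(k)) * miss      # misses strictly before each hit
    at_hit = cum_hit - miss_before                 # value after taking the hit step
    before_hit = np.concatenate([[0.0], cum_hit[:-1]]) - miss_before
    i_max = int(np.argmax(at_hit))
    i_min = int(np.argmin(before_hit))
    es_pos = float(at_hit[i_max])
    es_neg = float(before_hit[i_min])
    if es_pos >= -es_neg:
        return es_pos, i_max
    return es_neg, -(i_min + 1)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    bh_adjusted_p: float
    size: int
    leading_edge: list[str]


def gsea_preranked(ranking: pd.Series, sets: GeneSetCollection,
                   n_perm: int = 1000, seed: int = 0, weight: float = 1.0,
                   min_size: int = 10, max_size: int = 500) -> pd.DataFrame:
    """Preranked gene-set enrichment with a gene-permutation null.

    Parameters
    ----------
    ranking : Series mapping gene -> signed statistic (e.g. the DE Wald
        statistic); sorted internally, ties broken by gene ID.
    n_perm : permutations per set size; < 100 triggers a warning.
    weight : hit-step exponent on |stat| (1 = classic weighted, 0 = unweighted KS).

    Returns a DataFrame with columns set_name, size, es, nes, p_value,
    bh_adjusted_p, leading_edge (comma-joined genes).
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; permutation p values will be coarse", n_perm)
    ordered = _order_ranking(ranking)
    genes = np.asarray(ordered.index)
    stats = ordered.to_numpy()
    n = genes.size
    index_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    for name in sets.names():
        if len(sets.genes(name)) > n:
            raise ValueError(f"set {name!r} larger than the ranked universe")
    measured = sets.intersect(genes)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name in measured.names():
        members = measured.genes(name)
        k = len(members)
        if not (min_size <= k <= max_size):
            continue
        pos = np.sort(np.array([index_of[g] for g in members]))
        es, where = _es_from_positions(pos, stats, n, weight)
        if k not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                rpos = np.sort(rng.choice(n, size=k, replace=False))
                null[b], _ = _es_from_positions(rpos, stats, n, weight)
            null_cache[k] = null
        null = null_cache[k]
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.mean(np.abs(same_sign)) if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        if where >= 0:  # positive ES: hits up to and including the extremum
            le = [g for g in genes[: pos[where] + 1] if g in set(members)]
        else:
            j = -where - 1
            le = [g for g in genes[pos[j]:] if g in set(members)]
        rows.append({
            "set_name": name, "size": k, "es": es, "nes": nes,
            "p_value": p, "leading_edge": ",".join(le),
        })
    out = pd.DataFrame(rows, columns=["set_name", "size", "es", "nes", "p_value", "leading_edge"])
    out["bh_adjusted_p"] = (
        benjamini_hochberg(out["p_value"].to_numpy()) if len(out) else np.array([])
    )
    return out[["set_name", "size", "es", "nes", "p_value", "bh_adjusted_p", "leading_edge"]]


@dataclass
class ORAResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float


def hypergeom_ora(query: list[str] | set[str], gene_set: list[str] | set[str],
                  universe: list[str] | set[str], set_name: str = "set") -> ORAResult:
    """Upper-tail hypergeometric over-representation: P(X >= k)."""
    uni = set(universe)
    q = set(query) & uni
    s = set(gene_set) & uni
    if set(query) - uni or set(gene_set) - uni:
        raise ValueError("query and gene set must be subsets of the universe")
    if not q:
        raise ValueError("query is empty")
    k = len(q & s)
    p = float(hypergeom.sf(k - 1, len(uni), len(s), len(q)))
    return ORAResult(set_name, k, len(s), len(q), len(uni), min(p, 1.0))


def ora_table(query: list[str], sets: GeneSetCollection,
              universe: list[str]) -> pd.DataFrame:
    """Run the over-representation test against every set; BH across sets."""
    measured = sets.intersect(universe)
    rows = []
    for name in measured.names():
        r = hypergeom_ora(query, measured.genes(name), universe, set_name=name)
        rows.append({
            "set_name": name, "overlap": r.overlap, "set_size": r.set_size,
            "query_size": r.query_size, "universe_size": r.universe_size,
            "p_value": r.p_value,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_adjusted_p"] = benjamini_hochberg(out["p_value"].to_numpy())
    else:
        out["bh_adjusted_p"] = np.array([])
    return out
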