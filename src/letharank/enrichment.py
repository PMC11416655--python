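"""Pre-ranked GSEA and single-sample GSEA used to validate signatures and neighborhoods."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneMatrix, GeneSet
from .vulnerability import _pairwise_pearson

__all__ = ["GseaResult", "preranked_gsea", "ssgsea", "neighbor_validation"]


@dataclass(frozen=True)
class GseaResult:
    """Enrichment score, normalized score and permutation p-value for one set."""

    es: float
    nes: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.es <= 1.0 + 1e-12):
            raise ValueError(f"ES out of range: {self.es}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")


def _es_from_hits(
    hit_pos: np.ndarray, weights: np.ndarray, g: int
) -> np.ndarray:
    """Walking enrichment scores for one or many hit-index sets.

    ``hit_pos`` is (n_sets, m) with positions sorted ascending within each
    row into a ranking of length ``g``; ``weights`` holds the matching
    |stat|^p values. The running sum increments by weight/sum(weights) at a
    hit and decrements by 1/(g - m) at each miss; the ES is the extremum of
    the running sum, which is always attained immediately after a hit (for
    the maximum) or immediately before one / at the walk end (for the
    minimum), so only hit positions need to be visited.
    """
    hit_pos = np.atleast_2d(hit_pos)
    weights = np.atleast_2d(weights)
    n_sets, m = hit_pos.shape
    miss_step = 1.0 / (g - m)
    wsum = weights.sum(axis=1, keepdims=True)
    # guard all-zero weights (flat statistics): hits contribute equally
    flat = wsum[:, 0] == 0
    if flat.any():
        weights = weights.copy()
        weights[flat] = 1.0
        wsum = weights.sum(axis=1, keepdims=True)
    cum_w = np.cumsum(weights, axis=1) / wsum
    j = np.arange(m)
    # misses before (exclusive of) hit j: hit_pos - j
    peaks = cum_w - (hit_pos - j) * miss_step            # just after each hit
    dips = cum_w - weights / wsum - (hit_pos - j) * miss_step  # just before each hit
    es_max = peaks.max(axis=1)
    es_min = np.minimum(dips.min(axis=1), 0.0)
    return np.where(es_max >= -es_min, es_max, es_min)


def preranked_gsea(
    ranking: pd.Series,
    gene_set: GeneSet,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Pre-ranked GSEA of one gene set against a gene-level statistic.

    Parameters
    ----------
    ranking : statistic per gene (need not be pre-sorted; sorted descending
        internally, ties broken by gene id for determinism).
    gene_set : the query set; its intersection with the ranking must have
        2 <= m < G members.
    weight_exponent : hit increments are |stat|^p normalized by the in-set
        sum; misses decrement 1/(G - m).
    n_perm, seed : the permutation null draws random m-gene sets.

    Notes
    -----
    NES = ES / mean(|ES_perm|) over same-sign permutation scores; the
    p-value is (1 + #{same-sign perms with |ES_perm| >= |ES|}) /
    (1 + #same-sign perms), so it is never 0 and is uniform under the null.
    """
    stats_vec = ranking.dropna()
    g = len(stats_vec)
    members = gene_set.members & set(stats_vec.index)
    m = len(members)
    if m < 1:
        raise ValueError(f"set {gene_set.name!r} does not intersect the ranking")
    if m >= g:
        raise ValueError("set covers the whole ranking")
    order = sorted(stats_vec.index, key=lambda x: (-stats_vec[x], x))
    sorted_stats = stats_vec.loc[order].to_numpy(dtype=float)
    abs_w = np.abs(sorted_stats) ** weight_exponent
    hit_mask = np.fromiter((x in members for x in order), dtype=bool, count=g)
    hits = np.flatnonzero(hit_mask)
    es = float(_es_from_hits(hits[None, :], abs_w[hits][None, :], g)[0])

    rng = np.random.default_rng(seed)
    perm_pos = np.argpartition(rng.random((n_perm, g)), m - 1, axis=1)[:, :m]
    perm_pos.sort(axis=1)
    perm_w = abs_w[perm_pos]
    es_perm = _es_from_hits(perm_pos, perm_w, g)

    same_sign = es_perm >= 0 if es >= 0 else es_perm < 0
    n_same = int(same_sign.sum())
    if n_same:
        denom = float(np.abs(es_perm[same_sign]).mean())
        nes = es / denom if denom > 0 else 0.0
    else:
        nes = 0.0
    exceed = int((np.abs(es_perm[same_sign]) >= abs(es)).sum())
    p = (1 + exceed) / (1 + n_same)
    return GseaResult(es=es, nes=float(nes), p_value=float(p),
                      n_permutations=n_perm, seed=seed)


def ssgsea(
    expression: GeneMatrix,
    gene_set: GeneSet,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.Series:
    """Single-sample enrichment score of one gene set per sample.

    Within each sample, genes are ranked by expression (rank G = highest);
    the score is the sum over the ranking of the difference between the
    weighted in-set ECDF (weights rank^alpha) and the unweighted out-of-set
    ECDF. With ``normalize`` the scores are divided by their (max - min)
    across samples.
    """
    df = expression.df
    members = gene_set.members & set(df.index)
    if not members:
        raise ValueError(f"set {gene_set.name!r} does not overlap the expression genes")
    in_set = df.index.isin(members)
    scores = {}
    for sample in df.columns:
        vals = df[sample].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        v, mask = vals[ok], in_set[ok]
        g = len(v)
        m = int(mask.sum())
        if m == 0 or m == g:
            raise ValueError(f"set degenerate within sample {sample!r}")
        # descending order; rank magnitude g..1
        order = np.argsort(-v, kind="mergesort")
        hit = mask[order]
        rank_mag = np.arange(g, 0, -1, dtype=float)
        w = np.where(hit, rank_mag ** alpha, 0.0)
        ecdf_in = np.cumsum(w) / w.sum()
        ecdf_out = np.cumsum(~hit) / (g - m)
        scores[sample] = float(np.sum(ecdf_in - ecdf_out))
    out = pd.Series(scores, name=gene_set.name)
    if normalize:
        span = out.max() - out.min()
        if span > 0:
            out = out / span
    return out


def neighbor_validation(
    neighbor_set: GeneSet,
    expression: GeneMatrix,
    target: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """GSEA of a neighbor set against a correlation-derived ranking.

    Every gene's expression row is correlated (Pearson, pairwise-complete)
    with the per-cell-line ``target`` vector (e.g., a drug AUC profile or an
    anchor gene's dependency scores); the neighbor set is then tested against
    that correlation ranking with :func:`preranked_gsea`.
    """
    shared = [c for c in expression.col_ids if c in target.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared cell lines between expression and target")
    t = target.loc[shared].to_numpy(dtype=float)
    if np.nanstd(t) == 0:
        raise ValueError("target vector is constant; correlation undefined")
    r = _pairwise_pearson(expression.df[shared].to_numpy(), t)
    ranking = pd.Series(r, index=expression.df.index).dropna()
    return preranked_gsea(ranking, neighbor_set, weight_exponent=1.0,
                          n_perm=n_perm, seed=seed)
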