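"""Assembling the predictor matrix, embedding it, and ranking candidates.

The gene universe is the intersection of the genes carrying correlation
predictors and the genes carrying similarity predictors; each predictor
column is rank-normalized to [0, 1] (fractional ranks, ties averaged), which
neutralizes the scale mismatch between rank-difference similarity scores and
[-1, 1] correlations. The matrix is projected to 2-D with UMAP and genes are
ranked by Euclidean distance to a user-chosen anchor gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "build_predictor_matrix",
    "embed",
    "anchor_neighbors",
    "aggregate_score",
    "stability_analysis",
    "embedding_fidelity",
    "filter_candidates",
]


@dataclass
class Embedding:
    """2-D coordinates per gene plus the hyperparameters that produced them."""

    coords: pd.DataFrame  # index: gene ids; columns: x, y
    seed: int
    min_dist: float
    n_neighbors: int

    def __post_init__(self) -> None:
        if list(self.coords.columns) != ["x", "y"]:
            raise ValueError("embedding coordinates must have columns ['x', 'y']")
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValueError("embedding contains non-finite coordinates")


def _rank_normalize(col: pd.Series) -> pd.Series:
    """Fractional ranks (average ties) min-max scaled to [0, 1]."""
    r = col.rank(method="average")
    span = r.max() - r.min()
    if span == 0:
        return pd.Series(0.5, index=col.index)
    return (r - r.min()) / span


def build_predictor_matrix(
    corr_predictors: pd.DataFrame,
    sim_final: pd.DataFrame,
) -> pd.DataFrame:
    """Join correlation and similarity predictors into a normalized matrix.

    Parameters
    ----------
    corr_predictors : genes x 6 correlation columns (``expr_*`` / ``dep_*``).
    sim_final : genes x retained-profile final similarity scores.

    Returns
    -------
    Genes x (6 + retained) DataFrame, each column independently
    rank-normalized to [0, 1]. Genes outside the intersection of the two
    inputs, or with any missing predictor, are dropped and logged. Columns
    are ordered: correlation predictors first (input order), then similarity
    predictors (input order).
    """
    shared = corr_predictors.index.intersection(sim_final.index)
    if shared.empty:
        raise ValueError("no genes shared between correlation and similarity predictors")
    raw = pd.concat([corr_predictors.loc[shared], sim_final.loc[shared]], axis=1)
    complete = raw.dropna()
    dropped = len(raw) - len(complete)
    if dropped:
        logger.info("dropped %d genes with missing predictors", dropped)
    if complete.empty:
        raise ValueError("no genes with complete predictors")
    return complete.apply(_rank_normalize)


def embed(
    matrix: pd.DataFrame,
    min_dist: float = 0.05,
    n_neighbors: int = 15,
    seed: int = 0,
) -> Embedding:
    """2-D UMAP projection of the predictor matrix (Euclidean input metric).

    A fixed ``seed`` makes the projection deterministic on a fixed platform
    (UMAP runs single-threaded when a random state is supplied).
    """
    import umap  # deferred: numba JIT import is slow

    if len(matrix) < n_neighbors + 1:
        raise ValueError(
            f"need >= n_neighbors + 1 = {n_neighbors + 1} genes, got {len(matrix)}"
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="sklearn")
        reducer = umap.UMAP(
            n_components=2,
            min_dist=min_dist,
            n_neighbors=n_neighbors,
            metric="euclidean",
            random_state=seed,
        )
        xy = reducer.fit_transform(matrix.to_numpy(dtype=float))
    coords = pd.DataFrame(np.asarray(xy, dtype=float), index=matrix.index,
                          columns=["x", "y"])
    return Embedding(coords=coords, seed=seed, min_dist=min_dist,
                     n_neighbors=n_neighbors)


def anchor_neighbors(
    embedding: Embedding, anchor: str, k: int
) -> tuple[pd.DataFrame, GeneSet]:
    """Distances and ranks of every gene to the anchor, plus the top-k set.

    The anchor is excluded from its own ranking. Distance ties are broken
    lexicographically by gene id.
    """
    coords = embedding.coords
    if anchor not in coords.index:
        raise ValueError(f"anchor gene {anchor!r} absent from the embedding")
    delta = coords.to_numpy() - coords.loc[anchor].to_numpy()
    dist = pd.Series(np.hypot(delta[:, 0], delta[:, 1]), index=coords.index)
    dist = dist.drop(anchor)
    order = sorted(dist.index, key=lambda g: (dist[g], g))
    ranking = pd.DataFrame({"distance": dist.loc[order]})
    ranking["rank"] = np.arange(1, len(order) + 1)
    ranking.index.name = "gene"
    k = min(k, len(ranking))
    top = GeneSet(name=f"{anchor}_top{k}", members=frozenset(order[:k]))
    return ranking, top


def aggregate_score(
    corr_predictors: pd.DataFrame,
    sim_final: pd.DataFrame,
) -> pd.Series:
    """Single per-gene score from the raw (pre-normalization) predictors.

    a = mean of the expression correlations, b = mean of the dependency
    correlations, m = max(a, b); m is ranked ascending across genes, the
    mean of the similarity predictors is ranked ascending, and the score is
    the average of the two ranks (higher = stronger candidate; the gene
    topping both ranks scores N). Genes with any missing component are
    dropped.
    """
    expr_cols = [c for c in corr_predictors.columns if c.startswith("expr_")]
    dep_cols = [c for c in corr_predictors.columns if c.startswith("dep_")]
    if not expr_cols or not dep_cols:
        raise ValueError("correlation predictors must include expr_* and dep_* columns")
    shared = corr_predictors.index.intersection(sim_final.index)
    corr = corr_predictors.loc[shared].dropna()
    sim = sim_final.loc[shared].dropna()
    genes = corr.index.intersection(sim.index)
    if genes.empty:
        raise ValueError("no genes with complete predictors")
    a = corr.loc[genes, expr_cols].mean(axis=1)
    b = corr.loc[genes, dep_cols].mean(axis=1)
    m = pd.concat([a, b], axis=1).max(axis=1)
    r1 = m.rank(method="average")
    r2 = sim.loc[genes].mean(axis=1).rank(method="average")
    score = (r1 + r2) / 2.0
    score.name = "aggregate_score"
    return score.sort_values(ascending=False)


def stability_analysis(
    matrix: pd.DataFrame,
    anchor: str,
    k: int,
    n_seeds: int,
    min_dist: float = 0.05,
    n_neighbors: int = 15,
    master_seed: int = 0,
) -> pd.Series:
    """Fraction of re-seeded embeddings in which each gene stays a top-k neighbor.

    Seeds are ``master_seed + i`` for i in 0..n_seeds-1. The anchor itself is
    excluded; genes never retained report 0.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    counts = pd.Series(0.0, index=matrix.index.drop(anchor))
    for i in range(n_seeds):
        emb = embed(matrix, min_dist=min_dist, n_neighbors=n_neighbors,
                    seed=master_seed + i)
        _, top = anchor_neighbors(emb, anchor, k)
        counts.loc[counts.index.isin(top.members)] += 1.0
    return counts / n_seeds


def embedding_fidelity(
    matrix: pd.DataFrame,
    embedding: Embedding,
    n_pairs: int = 10000,
    seed: int = 0,
) -> float:
    """Spearman correlation of predictor-space vs embedding-space distances.

    Distances are compared over ``n_pairs`` gene pairs sampled uniformly with
    replacement (self-pairs excluded).
    """
    if n_pairs < 10:
        raise ValueError("n_pairs must be >= 10")
    genes = matrix.index.intersection(embedding.coords.index)
    x = matrix.loc[genes].to_numpy(dtype=float)
    y = embedding.coords.loc[genes].to_numpy(dtype=float)
    n = len(genes)
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n, size=n_pairs)
    ok = i != j
    i, j = i[ok], j[ok]
    d_pred = np.linalg.norm(x[i] - x[j], axis=1)
    d_emb = np.linalg.norm(y[i] - y[j], axis=1)
    rho, _ = sps.spearmanr(d_pred, d_emb)
    return float(rho)


def filter_candidates(
    neighbors: pd.DataFrame,
    dependency: GeneMatrix,
    citations: pd.DataFrame | None = None,
    druggable: set[str] | None = None,
    essentiality_threshold: float = -0.5,
    essential_fraction: float = 0.9,
) -> pd.DataFrame:
    """Annotate an anchor-neighbor ranking with candidate-selection flags.

    Flags (nothing is removed, only annotated):

    - ``pan_essential``: dependency below ``essentiality_threshold`` in at
      least ``essential_fraction`` of the cell lines with data.
    - ``previously_cited``: any nonzero citation count across the table's
      terms (genes absent from the table count as uncited).
    - ``druggable``: membership in the supplied list (False everywhere when
      no list is given).
    """
    out = neighbors.copy()
    dep = dependency.df.reindex(out.index)
    with np.errstate(invalid="ignore"):
        below = (dep < essentiality_threshold).sum(axis=1)
        n_obs = dep.notna().sum(axis=1)
        frac = below / n_obs.replace(0, np.nan)
    out["pan_essential"] = (frac >= essential_fraction).fillna(False)
    if citations is not None:
        cited = citations.sum(axis=1) > 0
        out["previously_cited"] = cited.reindex(out.index).fillna(False).astype(bool)
    else:
        out["previously_cited"] = False
    out["druggable"] = out.index.isin(druggable) if druggable else False
    return out
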