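"""Scoring knockdown signatures against drug-response profiles.

Each signature contributes a top-K ("up") and bottom-K ("down") gene set.
Every set is scored against every retained response profile with a
pre-ranked competitive two-sample test that inflates the variance by a fixed
inter-gene correlation (VIF = 1 + (m-1)*rho). Scores are aggregated per
knocked-down gene across its cell contexts, ranked within each profile, and
combined into a single rank-difference predictor: up-rank minus down-rank,
so N genes bound the predictor to [-(N-1), N-1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FoldChangeProfile, GeneSet, SignatureCompendium

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureSetPair",
    "EnrichmentScore",
    "extract_signature_sets",
    "camera_pr",
    "score_signatures",
    "aggregate_by_gene",
    "similarity_predictors",
]


@dataclass(frozen=True)
class SignatureSetPair:
    """Top-K and bottom-K gene sets extracted from one signature."""

    signature_id: str
    up: GeneSet
    down: GeneSet


@dataclass(frozen=True)
class EnrichmentScore:
    """Signed competitive-test statistic (positive = set up-shifted) and p-value."""

    statistic: float
    p_value: float
    m: int


def extract_signature_sets(
    compendium: SignatureCompendium, k: int
) -> list[SignatureSetPair]:
    """Top-k and bottom-k genes of each signature by z-score.

    Signatures with fewer than 2k non-missing genes are skipped with a
    warning. Ties in z-score are broken lexicographically by gene id; the two
    sets of a signature are disjoint by construction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = compendium.matrix.df
    genes = np.asarray(df.index)
    pairs: list[SignatureSetPair] = []
    for sig in df.columns:
        z = df[sig].to_numpy()
        ok = np.isfinite(z)
        if ok.sum() < 2 * k:
            logger.warning("signature %r has < %d non-missing genes; skipped", sig, 2 * k)
            continue
        g, v = genes[ok], z[ok]
        # sort by (-z, gene id): deterministic under ties
        order = np.lexsort((g, -v))
        up = frozenset(g[order[:k]])
        down = frozenset(g[order[-k:]])
        pairs.append(SignatureSetPair(
            signature_id=str(sig),
            up=GeneSet(name=f"{sig}|up", members=up, direction="up"),
            down=GeneSet(name=f"{sig}|down", members=down, direction="down"),
        ))
    return pairs


def _camera_batch(
    stats_vec: np.ndarray,
    set_ids: np.ndarray,
    gene_pos: np.ndarray,
    n_sets: int,
    rho: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized competitive test of many sets against one statistic vector.

    ``set_ids``/``gene_pos`` are parallel arrays mapping each set membership
    to a position in ``stats_vec``. Returns (t, p, m) per set; sets with
    m < 2 or m >= G get NaN.
    """
    g_total = len(stats_vec)
    total_sum = float(stats_vec.sum())
    total_sq = float((stats_vec ** 2).sum())
    m = np.bincount(set_ids, minlength=n_sets).astype(float)
    sum_in = np.bincount(set_ids, weights=stats_vec[gene_pos], minlength=n_sets)
    sq_in = np.bincount(set_ids, weights=stats_vec[gene_pos] ** 2, minlength=n_sets)
    m_out = g_total - m
    valid = (m >= 2) & (m_out >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_in = sum_in / m
        mean_out = (total_sum - sum_in) / m_out
        delta = mean_in - mean_out
        ss_in = sq_in - m * mean_in ** 2
        ss_out = (total_sq - sq_in) - m_out * mean_out ** 2
        s2 = (ss_in + ss_out) / (g_total - 2)
        vif = 1.0 + (m - 1.0) * rho
        se = np.sqrt(s2 * (vif / m + 1.0 / m_out))
        t = delta / se
    # zero pooled variance: no signal by definition
    t = np.where(np.isclose(s2, 0.0), 0.0, t)
    p = 2.0 * sps.t.sf(np.abs(t), df=g_total - 2)
    p = np.where(np.isclose(s2, 0.0), 1.0, p)
    t[~valid] = np.nan
    p[~valid] = np.nan
    return t, p, m.astype(int)


def camera_pr(gene_stats: pd.Series, gene_set: GeneSet, rho: float = 0.01) -> EnrichmentScore:
    """Competitive two-sample test of a gene set against a pre-ranked statistic.

    Compares the in-set mean statistic to the out-of-set mean with a pooled
    two-group variance (df = G - 2) and a variance inflation factor
    VIF = 1 + (m - 1) * rho for the in-set group:

        t = (mean_in - mean_out) / (s * sqrt(VIF/m + 1/(G - m)))

    With rho = 0 this reduces exactly to the ordinary pooled two-sample
    t-test. The p-value is two-sided; the statistic keeps its sign
    (positive = set shifted upward in the profile).
    """
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    stats_vec = gene_stats.dropna()
    universe = set(stats_vec.index)
    members = sorted(gene_set.members & universe)
    m = len(members)
    if m < 2:
        raise ValueError(
            f"set {gene_set.name!r} has {m} members in the universe; need >= 2"
        )
    if m >= len(stats_vec):
        raise ValueError("set covers the whole universe; competitive test undefined")
    pos = pd.Index(stats_vec.index).get_indexer(members)
    t, p, m_arr = _camera_batch(
        stats_vec.to_numpy(dtype=float),
        np.zeros(m, dtype=int), pos, 1, rho,
    )
    return EnrichmentScore(statistic=float(t[0]), p_value=float(p[0]), m=int(m_arr[0]))


def score_signatures(
    profiles: Sequence[FoldChangeProfile],
    sets: Sequence[SignatureSetPair],
    rho: float = 0.01,
) -> pd.DataFrame:
    """Score every up/down signature set against every profile's statistics.

    The per-gene statistic is the profile's log2FC. Returns a long DataFrame
    with columns signature_id, profile_id, up_score, down_score (signed test
    statistics); a set shrinking below 2 members within a profile's universe
    yields a missing score.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    if not sets:
        raise ValueError("no signature sets supplied")
    records = []
    for profile in profiles:
        stats_vec = profile.log2fc.dropna()
        universe = pd.Index(stats_vec.index)
        gene_to_pos = {g: i for i, g in enumerate(universe)}
        values = stats_vec.to_numpy(dtype=float)
        n_sets = 2 * len(sets)
        set_ids, gene_pos = [], []
        for i, pair in enumerate(sets):
            for offset, gs in ((0, pair.up), (1, pair.down)):
                sid = 2 * i + offset
                for gene in gs.members:
                    pos = gene_to_pos.get(gene)
                    if pos is not None:
                        set_ids.append(sid)
                        gene_pos.append(pos)
        if not set_ids:
            raise ValueError(
                f"no overlap between signature sets and profile {profile.profile_id!r}"
            )
        t, _, _ = _camera_batch(
            values, np.asarray(set_ids), np.asarray(gene_pos), n_sets, rho
        )
        for i, pair in enumerate(sets):
            records.append({
                "signature_id": pair.signature_id,
                "profile_id": profile.profile_id,
                "up_score": t[2 * i],
                "down_score": t[2 * i + 1],
            })
    return pd.DataFrame.from_records(records)


def aggregate_by_gene(
    raw_scores: pd.DataFrame,
    meta: pd.DataFrame,
    down_mode: str = "max",
) -> pd.DataFrame:
    """Collapse per-signature scores to one score per knocked-down gene.

    ``meta`` maps signature_id to perturbed_gene (as in a compendium). Both
    the up and down streams are aggregated by the maximum across a gene's
    cell-context signatures by default; ``down_mode='min'`` aggregates the
    down stream by minimum instead. Genes whose signatures all lack scores
    are dropped with a warning.
    """
    if down_mode not in ("max", "min"):
        raise ValueError("down_mode must be 'max' or 'min'")
    df = raw_scores.copy()
    gene_of = meta["perturbed_gene"]
    df["gene"] = df["signature_id"].map(gene_of)
    unknown = df["gene"].isna()
    if unknown.any():
        raise ValueError(
            f"signatures missing from metadata: {df.loc[unknown, 'signature_id'].unique()[:10]}"
        )
    grouped = df.groupby(["gene", "profile_id"])
    agg = grouped.agg(
        up_score=("up_score", "max"),
        down_score=("down_score", down_mode),
    ).reset_index()
    dead = agg["up_score"].isna() & agg["down_score"].isna()
    if dead.any():
        for gene in agg.loc[dead, "gene"].unique():
            logger.warning("KD gene %r has no surviving signature scores; dropped", gene)
        agg = agg[~dead]
    return agg


def similarity_predictors(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Rank-difference predictor per knocked-down gene and profile.

    Within each profile, up and down aggregated scores are ranked ascending
    with average ties; final = up_rank - down_rank, bounded by
    [-(N-1), N-1] for N genes. Scores missing in a profile are filled with
    that profile's median score before ranking (logged), which lands them at
    the median rank.

    Returns a long DataFrame (gene, profile_id, up_score, down_score,
    up_rank, down_rank, final).
    """
    up = aggregated.pivot(index="gene", columns="profile_id", values="up_score")
    down = aggregated.pivot(index="gene", columns="profile_id", values="down_score")
    if len(up) < 2:
        raise ValueError("need >= 2 knocked-down genes to rank")
    for name, frame in (("up", up), ("down", down)):
        n_missing = int(frame.isna().to_numpy().sum())
        if n_missing:
            logger.warning(
                "%d missing %s scores filled with per-profile medians", n_missing, name
            )
    up_f = up.fillna(up.median())
    down_f = down.fillna(down.median())
    up_rank = up_f.rank(axis=0, method="average")
    down_rank = down_f.rank(axis=0, method="average")
    final = up_rank - down_rank
    out = pd.concat(
        {
            "up_score": up, "down_score": down,
            "up_rank": up_rank, "down_rank": down_rank, "final": final,
        },
        axis=1,
    )
    long = out.stack(level=1, future_stack=True).reset_index()
    long.columns = ["gene", "profile_id"] + list(long.columns[2:])
    return long.sort_values(["gene", "profile_id"]).reset_index(drop=True)
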