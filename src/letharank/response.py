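"""Processing of the drug-response fold-change profiles.

Ranks genes by mean fold change across profiles, extracts top/bottom query
sets, counts recurrent differentially expressed genes, and runs the
consensus-based profile-selection step that drops the profiles least similar
to the rest before they are used as similarity predictors.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FoldChangeProfile, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "profiles_frame",
    "mean_fc_ranking",
    "recurrent_degs",
    "top_bottom_sets",
    "consensus_scores",
    "select_profiles",
]


def profiles_frame(profiles: Sequence[FoldChangeProfile]) -> pd.DataFrame:
    """Align profiles into a genes x profiles log2FC frame (missing = NaN)."""
    if not profiles:
        raise ValueError("no profiles supplied")
    ids = [p.profile_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate profile ids")
    return pd.DataFrame({p.profile_id: p.log2fc for p in profiles})


def mean_fc_ranking(profiles: Sequence[FoldChangeProfile]) -> pd.DataFrame:
    """Mean log2FC per gene across profiles with a dense descending rank.

    The mean is taken over the profiles where the gene is present. Rank 1 is
    the highest mean; ties are broken lexicographically by gene id so the
    ranking is a deterministic permutation of 1..G.
    """
    frame = profiles_frame(profiles)
    mean = frame.mean(axis=1, skipna=True).dropna()
    if mean.empty:
        raise ValueError("empty gene universe after alignment")
    order = sorted(mean.index, key=lambda g: (-mean[g], g))
    ranking = pd.DataFrame({"mean_log2fc": mean.loc[order]})
    ranking["rank"] = np.arange(1, len(order) + 1)
    ranking.index.name = "gene"
    return ranking


def recurrent_degs(
    profiles: Sequence[FoldChangeProfile],
    p_cut: float = 0.05,
    min_datasets: int = 3,
    direction: str = "up",
) -> GeneSet:
    """Genes significant (p < p_cut) with the requested sign in >= min_datasets profiles."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    for p in profiles:
        if p.p_value is None:
            raise ValueError(f"profile {p.profile_id!r} lacks p-values")
    counts: pd.Series = pd.Series(dtype=int)
    for p in profiles:
        sign_ok = p.log2fc > 0 if direction == "up" else p.log2fc < 0
        hit = ((p.p_value < p_cut) & sign_ok).astype(int)
        counts = counts.add(hit, fill_value=0)
    members = counts.index[counts >= min_datasets]
    if len(members) == 0:
        raise ValueError("no recurrent DEGs at the requested thresholds")
    return GeneSet(name=f"recurrent_{direction}_{min_datasets}plus",
                   members=frozenset(members), direction=direction)


def top_bottom_sets(ranking: pd.DataFrame, n: int) -> tuple[GeneSet, GeneSet]:
    """Top-n and bottom-n genes of a mean-FC ranking as disjoint up/down sets."""
    g = len(ranking)
    if n < 1 or n > g // 2:
        raise ValueError(f"n must be in [1, G/2] = [1, {g // 2}], got {n}")
    ordered = ranking.sort_values("rank").index
    up = GeneSet(name=f"top{n}", members=frozenset(ordered[:n]), direction="up")
    down = GeneSet(name=f"bottom{n}", members=frozenset(ordered[-n:]), direction="down")
    return up, down


def consensus_scores(profiles: Sequence[FoldChangeProfile]) -> pd.DataFrame:
    """Per-profile similarity to the consensus of all profiles.

    For each ordered pair of profiles, Pearson r is computed on the genes
    shared by that pair. Each profile's raw score is the sum of its positive
    correlations to all other profiles (negative correlations and the self
    term are excluded), and raw scores are min-max normalized to [0, 100].
    If all raw scores are equal, every profile gets 100.

    Returns a DataFrame indexed by profile id with columns ``raw`` and
    ``normalized``.
    """
    m = len(profiles)
    if m < 3:
        raise ValueError(f"need >= 3 profiles for consensus scoring, got {m}")
    frame = profiles_frame(profiles)
    ids = list(frame.columns)
    raw = np.zeros(m)
    for i in range(m):
        for j in range(i + 1, m):
            pair = frame[[ids[i], ids[j]]].dropna()
            if len(pair) < 3:
                continue
            r = float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
            if np.isfinite(r) and r > 0:
                raw[i] += r
                raw[j] += r
    span = raw.max() - raw.min()
    if span == 0:
        logger.warning("all profiles equally consensual; normalized scores all 100")
        normalized = np.full(m, 100.0)
    else:
        normalized = 100.0 * (raw - raw.min()) / span
    out = pd.DataFrame({"raw": raw, "normalized": normalized}, index=ids)
    out.index.name = "profile_id"
    return out


def select_profiles(scores: pd.DataFrame, drop_count: int) -> list[str]:
    """Retain the profiles with the highest normalized consensus scores.

    Drops the ``drop_count`` lowest-scoring profiles; ties are broken
    lexicographically by profile id (lower id dropped first). Returns retained
    profile ids in their original order.
    """
    m = len(scores)
    if not (0 <= drop_count < m):
        raise ValueError(f"drop_count must be in [0, {m - 1}], got {drop_count}")
    if drop_count == 0:
        return list(scores.index)
    if scores["normalized"].nunique() == 1:
        logger.warning("degenerate consensus scores; dropping by id order only")
    order = sorted(scores.index, key=lambda pid: (scores.at[pid, "normalized"], pid))
    dropped = set(order[:drop_count])
    return [pid for pid in scores.index if pid not in dropped]
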