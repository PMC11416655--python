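"""Offline citation-based validation of predictor combinations.

Works entirely from a pre-built gene x term citation-count table: scores
gene sets by the percentage of members with any citation for each term,
exhaustively scans every non-empty subset of the similarity predictors
(always combined with the correlation predictors), and builds a random-set
null distribution for empirical p-values.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneSet
from .integration import _rank_normalize

__all__ = ["cited_fraction", "combination_scan", "random_null"]


def cited_fraction(
    genes: GeneSet | Sequence[str],
    table: pd.DataFrame,
    terms: Sequence[str] | None = None,
) -> pd.Series:
    """Percentage of the set's genes with a nonzero count for each term.

    Genes absent from the table count as uncited.
    """
    members = sorted(genes.members) if isinstance(genes, GeneSet) else sorted(set(genes))
    if not members:
        raise ValueError("empty gene set")
    terms = list(terms) if terms is not None else list(table.columns)
    unknown = [t for t in terms if t not in table.columns]
    if unknown:
        raise ValueError(f"terms absent from the citation table: {unknown}")
    counts = table.reindex(members).fillna(0)
    pct = 100.0 * (counts[terms] > 0).sum(axis=0) / len(members)
    pct.name = "cited_pct"
    return pct


def combination_scan(
    corr_predictors: pd.DataFrame,
    sim_final: pd.DataFrame,
    table: pd.DataFrame,
    top_n: int = 50,
    terms: Sequence[str] | None = None,
    strategy: str = "mean",
) -> pd.DataFrame:
    """Cited percentages for every non-empty similarity-predictor subset.

    For each of the 2^M - 1 subsets of the M similarity predictors, the
    correlation predictors plus the selected similarity columns are
    rank-normalized, genes are ordered by the chosen strategy (``mean`` of
    the selected columns, or ``min-rank``: maximum of the per-column
    normalized ranks), and the ``top_n`` highest genes are scored with
    :func:`cited_fraction`. One output row per combination.
    """
    if strategy not in ("mean", "min-rank"):
        raise ValueError("strategy must be 'mean' or 'min-rank'")
    m = sim_final.shape[1]
    if m > 20:
        raise ValueError(f"refusing to enumerate 2^{m} - 1 combinations (M > 20)")
    shared = corr_predictors.index.intersection(sim_final.index)
    raw = pd.concat([corr_predictors.loc[shared], sim_final.loc[shared]], axis=1).dropna()
    if top_n > len(raw):
        raise ValueError(f"top_n={top_n} exceeds the {len(raw)}-gene universe")
    normalized = raw.apply(_rank_normalize)
    corr_cols = list(corr_predictors.columns)
    sim_cols = list(sim_final.columns)
    corr_part = normalized[corr_cols].to_numpy()
    sim_part = normalized[sim_cols].to_numpy()
    genes = np.asarray(normalized.index)
    terms = list(terms) if terms is not None else list(table.columns)

    rows = []
    for size in range(1, m + 1):
        for combo in combinations(range(m), size):
            sel = sim_part[:, list(combo)]
            if strategy == "mean":
                score = np.column_stack([corr_part, sel]).mean(axis=1)
            else:
                score = np.column_stack([corr_part, sel]).min(axis=1)
            # descending score, gene id tiebreak
            order = np.lexsort((genes, -score))
            top = genes[order[:top_n]]
            pct = cited_fraction(list(top), table, terms)
            row = {"combination": "+".join(sim_cols[i] for i in combo),
                   "n_similarity": size}
            row.update({f"pct_{t}": pct[t] for t in terms})
            rows.append(row)
    return pd.DataFrame(rows)


def random_null(
    universe: Sequence[str],
    n_sets: int,
    set_size: int,
    table: pd.DataFrame,
    terms: Sequence[str] | None = None,
    seed: int = 0,
    observed: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Null cited-percentage distribution from random gene sets.

    Draws ``n_sets`` uniform without-replacement sets of ``set_size`` genes
    from the universe and scores each with :func:`cited_fraction`. When an
    ``observed`` per-term percentage vector is supplied, returns the
    add-one empirical p-value per term:
    p = (1 + #{null >= observed}) / (1 + n_sets).
    """
    universe = sorted(set(universe))
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe")
    terms = list(terms) if terms is not None else list(table.columns)
    rng = np.random.default_rng(seed)
    arr = np.asarray(universe)
    records = []
    for _ in range(n_sets):
        draw = rng.choice(arr, size=set_size, replace=False)
        records.append(cited_fraction(list(draw), table, terms))
    null = pd.DataFrame(records).reset_index(drop=True)
    p_values = None
    if observed is not None:
        p_values = pd.Series({
            t: (1 + int((null[t] >= observed[t]).sum())) / (1 + n_sets)
            for t in terms
        })
        p_values.name = "empirical_p"
    return null, p_values
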