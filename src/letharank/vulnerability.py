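"""Dose-response modelling and per-gene vulnerability-correlation predictors.

The workflow: fit a four-parameter log-logistic curve per (cell line, drug),
summarize each curve as a normalized area under the viability curve in
log10-dose space (AUC in [0, 1], high = resistant), then correlate every
gene's expression and dependency values against the per-drug AUC vectors.
With three drugs and two data modalities this yields six correlation
predictors per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .io import GeneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseFit",
    "ll4",
    "fit_dose_response",
    "compute_auc",
    "auc_table",
    "correlation_predictors",
    "threshold_gene_lists",
]


@dataclass
class DoseResponseFit:
    """Four-parameter log-logistic fit f(x) = c + (d-c) / (1 + exp(b*(ln x - ln e)))."""

    b: float
    c: float
    d: float
    e: float
    rss: float
    converged: bool
    degenerate: bool = False

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.b, self.c, self.d, self.e)

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return ll4(np.asarray(dose, dtype=float), self.b, self.c, self.d, self.e)


def ll4(x: np.ndarray, b: float, c: float, d: float, e: float) -> np.ndarray:
    """Evaluate the 4-parameter log-logistic function at positive doses x."""
    with np.errstate(over="ignore"):
        return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


def fit_dose_response(doses: np.ndarray, viability: np.ndarray) -> DoseResponseFit:
    """Least-squares LL.4 fit with deterministic multi-start initialization.

    Parameters
    ----------
    doses : array of positive concentrations (replicates allowed).
    viability : matching array of viabilities in percent of control (>= 0).

    Returns
    -------
    DoseResponseFit with ``c <= d`` after canonicalization. All-identical
    viability yields a flat fit (c = d = mean) flagged degenerate.

    Raises
    ------
    ValueError if fewer than 4 distinct doses are supplied or inputs are invalid.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.shape != viability.shape:
        raise ValueError("doses and viability must have the same length")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if np.any(viability < 0):
        raise ValueError("viability must be non-negative")
    if len(np.unique(doses)) < 4:
        raise ValueError(
            f"need >= 4 distinct doses, got {len(np.unique(doses))}"
        )
    if np.allclose(viability, viability[0]):
        mean = float(viability[0])
        return DoseResponseFit(b=1.0, c=mean, d=mean, e=float(np.median(doses)),
                               rss=0.0, converged=True, degenerate=True)

    logx = np.log(doses)

    def residuals(theta: np.ndarray) -> np.ndarray:
        b, c, d, log_e = theta
        with np.errstate(over="ignore"):
            pred = c + (d - c) / (1.0 + np.exp(b * (logx - log_e)))
        return pred - viability

    lo = np.array([-50.0, 0.0, 0.0, np.log(doses.min()) - 5.0])
    hi = np.array([50.0, 120.0, 120.0, np.log(doses.max()) + 5.0])
    c0 = float(np.clip(viability.min(), 0.0, 120.0))
    d0 = float(np.clip(viability.max(), 0.0, 120.0))
    # e started at each observed dose quantile; b at a few magnitudes/signs
    e_starts = np.quantile(np.unique(doses), [0.1, 0.3, 0.5, 0.7, 0.9])
    best: DoseResponseFit | None = None
    for e0 in e_starts:
        for b0 in (0.5, 1.0, 2.0, -1.0):
            theta0 = np.clip(np.array([b0, c0, d0, np.log(e0)]), lo, hi)
            try:
                sol = optimize.least_squares(
                    residuals, theta0, bounds=(lo, hi),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
                )
            except Exception:  # pragma: no cover - numerical failure guard
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best.rss - 1e-15:
                b, c, d, log_e = sol.x
                if c > d:  # canonical orientation: c is the lower asymptote
                    c, d, b = d, c, -b
                best = DoseResponseFit(b=float(b), c=float(c), d=float(d),
                                       e=float(np.exp(log_e)), rss=rss,
                                       converged=bool(sol.success))
    if best is None:
        raise RuntimeError("all LL.4 starts failed")
    tol = 1e-8 * max(1.0, float(np.sum(viability ** 2)))
    if not best.converged and best.rss > tol:
        logger.warning("LL.4 fit did not converge (rss=%.3g)", best.rss)
    return best


def compute_auc(
    fit_or_points: DoseResponseFit | tuple[np.ndarray, np.ndarray],
    dose_range: tuple[float, float],
    n_points: int = 256,
) -> float:
    """Normalized area under the viability curve over a log10-dose range.

    AUC = integral of viability d(log10 dose) over [lo, hi], divided by
    (log10 range x 100), so constant 100% viability gives exactly 1.0.
    Viability above 100 is clipped to 100 before integration; the fitted
    curve is sampled at ``n_points`` (>= 100) uniform log10-dose points.
    """
    lo, hi = float(dose_range[0]), float(dose_range[1])
    if lo <= 0 or hi <= 0:
        raise ValueError("dose range must be positive")
    if hi <= lo:
        raise ValueError("zero-width or inverted dose range")
    if isinstance(fit_or_points, DoseResponseFit):
        n_points = max(int(n_points), 100)
        grid = np.logspace(np.log10(lo), np.log10(hi), n_points)
        viab = fit_or_points.predict(grid)
        logd = np.log10(grid)
    else:
        doses, viab = fit_or_points
        doses = np.asarray(doses, dtype=float)
        viab = np.asarray(viab, dtype=float)
        if len(doses) < 2:
            raise ValueError("need >= 2 curve points")
        order = np.argsort(doses)
        logd, viab = np.log10(doses[order]), viab[order]
    viab = np.clip(viab, 0.0, 100.0)
    area = float(np.trapezoid(viab, logd))
    return area / ((logd[-1] - logd[0]) * 100.0)


def auc_table(viability: pd.DataFrame, n_points: int = 256) -> pd.DataFrame:
    """Fit and integrate every (cell line, drug) series of a viability table.

    ``viability`` is long-format with columns cell_line, drug, dose, viability.
    Returns a cell_line x drug table of AUCs in [0, 1].
    """
    required = {"cell_line", "drug", "dose", "viability"}
    if not required.issubset(viability.columns):
        raise ValueError(f"viability table must have columns {sorted(required)}")
    records = {}
    for (line, drug), grp in viability.groupby(["cell_line", "drug"], sort=True):
        fit = fit_dose_response(grp["dose"].to_numpy(), grp["viability"].to_numpy())
        rng = (float(grp["dose"].min()), float(grp["dose"].max()))
        records[(line, drug)] = compute_auc(fit, rng, n_points=n_points)
    table = pd.Series(records).unstack()
    table.index.name = "cell_line"
    table.columns.name = "drug"
    return table


def _pairwise_pearson(values: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``values`` vs ``target`` on pairwise-complete pairs.

    Rows with < 3 complete pairs or zero variance yield NaN.
    """
    mask = np.isfinite(values) & np.isfinite(target)[None, :]
    x = np.where(mask, values, 0.0)
    t = np.where(mask, target[None, :], 0.0)
    n = mask.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = x.sum(axis=1) / n
        mt = t.sum(axis=1) / n
        xc = np.where(mask, values - mx[:, None], 0.0)
        tc = np.where(mask, target[None, :] - mt[:, None], 0.0)
        cov = (xc * tc).sum(axis=1)
        vx = (xc ** 2).sum(axis=1)
        vt = (tc ** 2).sum(axis=1)
        r = cov / np.sqrt(vx * vt)
    r[n < 3] = np.nan
    return r


def correlation_predictors(
    expression: GeneMatrix,
    dependency: GeneMatrix,
    auc: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene Pearson correlations of expression and dependency to drug AUCs.

    Parameters
    ----------
    expression, dependency : genes x cell lines matrices.
    auc : cell_line x drug AUC table.

    Returns
    -------
    DataFrame indexed by gene with one ``expr_<drug>`` and one ``dep_<drug>``
    column per drug; the gene index is the union of both input matrices.
    Correlations use pairwise-complete observations; genes with fewer than 3
    complete pairs are missing.
    """
    frames = []
    for prefix, matrix in (("expr", expression), ("dep", dependency)):
        shared = [c for c in matrix.col_ids if c in auc.index]
        if len(shared) < 3:
            raise ValueError(
                f"need >= 3 shared cell lines between {prefix} matrix and AUC table; "
                f"matrix lines: {matrix.col_ids[:10]}, AUC lines: {list(auc.index)[:10]}"
            )
        sub = matrix.df[shared]
        cols = {}
        for drug in auc.columns:
            target = auc.loc[shared, drug].to_numpy(dtype=float)
            cols[f"{prefix}_{drug}"] = _pairwise_pearson(sub.to_numpy(), target)
        frames.append(pd.DataFrame(cols, index=sub.index))
    return pd.concat(frames, axis=1)


def threshold_gene_lists(
    predictors: pd.DataFrame,
    threshold: float,
    prefix: str = "expr",
) -> dict:
    """Per-drug high/low gene lists at a strict |r| threshold, plus intersections.

    ``predictors`` is the output of :func:`correlation_predictors`; ``prefix``
    selects the modality (``expr`` or ``dep``). Genes with r > threshold go in
    the per-drug ``high`` lists, r < -threshold in ``low``; ``high_all`` /
    ``low_all`` are the intersections across all drugs. Inequalities are strict.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    cols = [c for c in predictors.columns if c.startswith(prefix + "_")]
    high: dict[str, list[str]] = {}
    low: dict[str, list[str]] = {}
    for col in cols:
        drug = col[len(prefix) + 1:]
        r = predictors[col]
        high[drug] = sorted(r.index[r > threshold])
        low[drug] = sorted(r.index[r < -threshold])
    high_all = sorted(set.intersection(*(set(v) for v in high.values()))) if high else []
    low_all = sorted(set.intersection(*(set(v) for v in low.values()))) if low else []
    return {"high": high, "low": low, "high_all": high_all, "low_all": low_all}
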