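"""Readers, writers and domain containers for every external format the pipeline touches.

Formats handled here: TSV/CSV matrices (expression, dependency, citation tables),
GCT 1.2 / 1.3 (perturbation-signature compendia), GMT (gene sets), long-format
TSV fold-change tables, and the TSV/JSON report writer. All writers are paired
with a reader that re-reads their output losslessly for finite floats.

Gene identifiers are matched as case-sensitive exact strings; no alias
resolution is performed. Missing values are propagated, never imputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "GeneMatrix",
    "SignatureCompendium",
    "FoldChangeProfile",
    "GeneSet",
    "PipelineConfig",
    "read_matrix",
    "write_matrix",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "read_profiles",
    "write_profiles",
    "read_citations",
    "write_citations",
    "write_report",
]

#: perturbation types treated as gene knockdowns (require a perturbed_gene)
KNOCKDOWN_TYPES = ("trt_sh", "trt_sh.cgs", "trt_xpr", "knockdown")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

class GeneMatrix:
    """A genes x samples numeric matrix with unique string identifiers.

    Thin validated wrapper around a :class:`pandas.DataFrame` whose index
    holds gene ids and whose columns hold sample / cell-line ids. Missing
    values (NaN) are allowed and propagated.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        _check_unique(df.index, "row")
        _check_unique(df.columns, "column")
        self.df = df.astype(float)

    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


@dataclass
class SignatureCompendium:
    """Perturbation z-score matrix plus per-signature metadata.

    ``matrix`` is genes x signatures; ``meta`` is indexed by signature id with
    columns ``perturbed_gene``, ``cell_line`` and ``perturbation_type``.
    """

    matrix: GeneMatrix
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        meta = self.meta.copy()
        meta.index = meta.index.astype(str)
        for col in ("perturbed_gene", "cell_line", "perturbation_type"):
            if col not in meta.columns:
                meta[col] = ""
            meta[col] = meta[col].fillna("").astype(str)
        missing = [s for s in self.matrix.col_ids if s not in meta.index]
        if missing:
            raise ValueError(
                f"signatures without metadata records: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        meta = meta.loc[self.matrix.col_ids]
        is_kd = meta["perturbation_type"].isin(KNOCKDOWN_TYPES) | (
            meta["perturbation_type"] == ""
        )
        offenders = meta.index[is_kd & (meta["perturbed_gene"] == "")].tolist()
        if offenders:
            raise ValueError(
                f"knockdown signatures lacking a perturbed_gene: {offenders[:10]}"
                + ("..." if len(offenders) > 10 else "")
            )
        self.meta = meta

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FoldChangeProfile:
    """Per-treatment gene-level log2 fold changes with optional p-values."""

    profile_id: str
    log2fc: pd.Series
    p_value: pd.Series | None = None

    def __post_init__(self) -> None:
        s = self.log2fc.copy()
        s.index = s.index.astype(str)
        if s.index.duplicated().any():
            dupes = s.index[s.index.duplicated()].unique().tolist()
            raise ValueError(
                f"profile {self.profile_id!r} has duplicate gene ids: {dupes[:10]}"
            )
        self.log2fc = s.astype(float)
        if self.p_value is not None:
            p = self.p_value.copy()
            p.index = p.index.astype(str)
            p = p.reindex(s.index).astype(float)
            finite = p.dropna()
            if ((finite < 0) | (finite > 1)).any():
                raise ValueError(
                    f"profile {self.profile_id!r} has p-values outside [0, 1]"
                )
            self.p_value = p

    @property
    def genes(self) -> pd.Index:
        return self.log2fc.index


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids with an optional direction tag."""

    name: str
    members: frozenset[str]
    direction: str = "none"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.direction not in ("up", "down", "none"):
            raise ValueError(f"invalid direction {self.direction!r}")
        object.__setattr__(self, "members", frozenset(str(m) for m in self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters; every CLI flag overrides these."""

    set_size: int = 20                  # K: genes per up/down signature set
    inter_gene_correlation: float = 0.01  # rho-bar for the competitive set test
    drop_count: int = 3                 # similarity predictors dropped by consensus
    umap_min_dist: float = 0.05
    umap_n_neighbors: int = 15
    neighborhood_k: int = 75
    n_stability_seeds: int = 500
    gsea_permutations: int = 1000
    ssgsea_alpha: float = 0.25
    correlation_threshold: float = 0.65
    top_n_textmine: int = 50
    random_sets: int = 2000
    random_set_size: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.set_size < 1:
            raise ValueError("set_size must be >= 1")
        if not (0 <= self.inter_gene_correlation < 1):
            raise ValueError("inter_gene_correlation must be in [0, 1)")
        if self.drop_count < 0:
            raise ValueError("drop_count must be >= 0")
        if self.umap_min_dist <= 0:
            raise ValueError("umap_min_dist must be > 0")
        for name in (
            "umap_n_neighbors",
            "neighborhood_k",
            "n_stability_seeds",
            "gsea_permutations",
            "top_n_textmine",
            "random_sets",
            "random_set_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not (0 < self.correlation_threshold < 1):
            raise ValueError("correlation_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        pipeline = data.get("pipeline", data)
        kwargs = {k: v for k, v in pipeline.items() if k in known}
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"pipeline": dataclasses.asdict(self)}, fh, sort_keys=True)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# TSV/CSV matrices
# ---------------------------------------------------------------------------

def _check_unique(ids: Iterable[str], kind: str) -> None:
    idx = pd.Index(ids)
    if idx.duplicated().any():
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {kind} identifiers: {dupes[:10]}")


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _to_float(s) -> float:
    try:
        return float(s)
    except (TypeError, ValueError):
        return np.nan


def _numeric_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Exact (correctly rounded) string-to-float conversion; junk becomes NaN."""
    return df.apply(lambda col: col.map(_to_float)).astype(float)


def read_matrix(path: str | Path, rows_are_genes: bool = True) -> GeneMatrix:
    """Read a TSV/CSV with one header row of column ids and first column of row ids.

    Non-numeric cells become missing. Duplicate row or column ids and empty
    files are hard errors.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"empty matrix file: {path}")
    col_ids = header.rstrip("\n").split(sep)[1:]
    _check_unique(col_ids, "column")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty and df.shape[1] == 0:
        raise ValueError(f"empty matrix file: {path}")
    df.index = df.index.astype(str)
    _check_unique(df.index, "row")
    df.columns = col_ids
    df = _numeric_frame(df)
    if not rows_are_genes:
        df = df.T
    return GeneMatrix(df)


def _float_repr(v: float) -> str:
    # shortest round-trip representation; plain float repr survives re-parsing
    return repr(float(v))


def write_matrix(matrix: GeneMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, sep=_sep_for(path), index_label="id",
                     float_format=_float_repr)


# ---------------------------------------------------------------------------
# GCT 1.2 / 1.3
# ---------------------------------------------------------------------------

#: column-annotation names mapped onto the meta table
_GCT_META_FIELDS = {
    "pert_iname": "perturbed_gene",
    "perturbed_gene": "perturbed_gene",
    "cell_id": "cell_line",
    "cell_line": "cell_line",
    "pert_type": "perturbation_type",
    "perturbation_type": "perturbation_type",
}


def read_gct(path: str | Path, meta_path: str | Path | None = None) -> SignatureCompendium:
    """Read a GCT 1.2 or 1.3 text file into a :class:`SignatureCompendium`.

    For GCT 1.2 the signature metadata is taken from ``meta_path`` (or a
    sibling ``<path>.meta.tsv`` keyed by signature_id, if present); a GCT 1.3
    file may embed it as column annotations (``pert_iname``, ``cell_id``,
    ``pert_type``). When no metadata is available anywhere, each signature
    defaults to ``perturbed_gene = signature_id`` so the compendium remains
    usable for format-level work.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError(f"empty GCT file: {path}")
    version = lines[0].strip()
    if version not in ("#1.2", "#1.3"):
        raise ValueError(f"unsupported GCT version line {version!r} in {path}")
    dims = lines[1].split("\t")
    if version == "#1.2":
        n_rows, n_cols = int(dims[0]), int(dims[1])
        n_rmeta, n_cmeta = 0, 0
    else:
        n_rows, n_cols, n_rmeta, n_cmeta = (int(x) for x in dims[:4])
    header = lines[2].split("\t")
    if version == "#1.2":
        sig_ids = header[2:]
    else:
        sig_ids = header[1 + n_rmeta:]
    if len(sig_ids) != n_cols:
        raise ValueError(
            f"GCT dimension line declares {n_cols} columns but header has {len(sig_ids)}"
        )
    _check_unique(sig_ids, "signature")

    col_meta: dict[str, list[str]] = {}
    body_start = 3
    if version == "#1.3":
        for i in range(n_cmeta):
            fields = lines[3 + i].split("\t")
            name = fields[0]
            col_meta[name] = fields[1 + n_rmeta:]
        body_start = 3 + n_cmeta

    gene_ids: list[str] = []
    rows: list[list[str]] = []
    for ln in lines[body_start:]:
        if not ln.strip():
            continue
        fields = ln.split("\t")
        gene_ids.append(fields[0])
        rows.append(fields[1 + n_rmeta + (1 if version == "#1.2" else 0):])
    if len(gene_ids) != n_rows:
        raise ValueError(
            f"GCT dimension line declares {n_rows} rows but file has {len(gene_ids)}"
        )
    _check_unique(gene_ids, "gene")
    values = pd.DataFrame(rows, index=gene_ids, columns=sig_ids)
    matrix = GeneMatrix(_numeric_frame(values))

    meta = pd.DataFrame(index=pd.Index(sig_ids, name="signature_id"))
    for raw, canon in _GCT_META_FIELDS.items():
        if raw in col_meta and canon not in meta.columns:
            meta[canon] = col_meta[raw]
    if meta_path is None:
        sibling = Path(str(path) + ".meta.tsv")
        meta_path = sibling if sibling.exists() else None
    if meta_path is not None:
        ext = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
        ext.index = ext.index.astype(str)
        for raw, canon in _GCT_META_FIELDS.items():
            if raw in ext.columns:
                meta[canon] = ext[raw].reindex(meta.index)
    if "perturbed_gene" not in meta.columns:
        logger.warning(
            "no signature metadata for %s; defaulting perturbed_gene to signature id",
            path,
        )
        meta["perturbed_gene"] = meta.index
        meta["perturbation_type"] = "unknown"
    return SignatureCompendium(matrix=matrix, meta=meta)


def write_gct(compendium: SignatureCompendium, path: str | Path) -> None:
    """Write a compendium as GCT 1.3 with embedded column annotations."""
    df = compendium.matrix.df
    meta = compendium.meta
    n_rows, n_cols = df.shape
    ann = [("pert_iname", "perturbed_gene"), ("cell_id", "cell_line"),
           ("pert_type", "perturbation_type")]
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{n_rows}\t{n_cols}\t0\t{len(ann)}\n")
        fh.write("id\t" + "\t".join(df.columns) + "\n")
        for raw, canon in ann:
            vals = meta[canon].reindex(df.columns).fillna("").astype(str)
            fh.write(raw + "\t" + "\t".join(vals) + "\n")
        for gene, row in zip(df.index, df.to_numpy()):
            fh.write(gene + "\t" + "\t".join(_float_repr(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file (name, description, tab-separated members).

    Lines with fewer than one member are skipped with a logged warning.
    A trailing ``|up`` / ``|down`` suffix on the description field restores
    the direction tag written by :func:`write_gmt`.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            name, desc = fields[0], fields[1] if len(fields) > 1 else ""
            members = [m for m in fields[2:] if m]
            if not members:
                logger.warning("GMT line %d (%r) has no members; skipped", lineno, name)
                continue
            direction = "none"
            if desc.endswith("|up"):
                direction = "up"
            elif desc.endswith("|down"):
                direction = "down"
            sets.append(GeneSet(name=name, members=frozenset(members), direction=direction))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            desc = f"na|{gs.direction}" if gs.direction != "none" else "na"
            fh.write(gs.name + "\t" + desc + "\t" + "\t".join(sorted(gs.members)) + "\n")


# ---------------------------------------------------------------------------
# Fold-change profiles (long TSV) and citation tables
# ---------------------------------------------------------------------------

def read_profiles(path: str | Path) -> list[FoldChangeProfile]:
    """Read a long TSV (profile_id, gene, log2fc[, p_value]) into profiles."""
    df = pd.read_csv(path, sep="\t", dtype={"profile_id": str, "gene": str},
                     float_precision="round_trip")
    required = {"profile_id", "gene", "log2fc"}
    if not required.issubset(df.columns):
        raise ValueError(f"profile table must have columns {sorted(required)}")
    profiles = []
    for pid, grp in df.groupby("profile_id", sort=True):
        fc = pd.Series(grp["log2fc"].to_numpy(), index=grp["gene"].to_numpy())
        pv = None
        if "p_value" in grp.columns and grp["p_value"].notna().any():
            pv = pd.Series(grp["p_value"].to_numpy(), index=grp["gene"].to_numpy())
        profiles.append(FoldChangeProfile(profile_id=str(pid), log2fc=fc, p_value=pv))
    return profiles


def write_profiles(profiles: Sequence[FoldChangeProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        df = pd.DataFrame({
            "profile_id": p.profile_id,
            "gene": p.log2fc.index,
            "log2fc": p.log2fc.to_numpy(),
        })
        df["p_value"] = p.p_value.to_numpy() if p.p_value is not None else np.nan
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format=_float_repr)


def read_citations(path: str | Path) -> pd.DataFrame:
    """Read a long TSV (gene, term, count) into a genes x terms count table."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "term": str})
    required = {"gene", "term", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"citation table must have columns {sorted(required)}")
    table = df.pivot_table(index="gene", columns="term", values="count",
                           aggfunc="sum", fill_value=0)
    if (table.to_numpy() < 0).any():
        raise ValueError("citation counts must be non-negative")
    return table.astype(int)


def write_citations(table: pd.DataFrame, path: str | Path) -> None:
    long = table.reset_index().melt(id_vars="gene", var_name="term", value_name="count")
    long = long.sort_values(["gene", "term"]).reset_index(drop=True)
    long.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Final report
# ---------------------------------------------------------------------------

#: leading report columns, in contract order
_REPORT_LEAD = ["gene", "distance", "rank"]


def write_report(table: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    """Write the final candidate table sorted by distance with ranks 1..n.

    Ties in distance are broken lexicographically by gene id so output is
    deterministic. Column order: gene, distance, rank, then everything else
    in the input's order.
    """
    if "gene" not in table.columns or "distance" not in table.columns:
        raise ValueError("report table requires 'gene' and 'distance' columns")
    out = table.sort_values(["distance", "gene"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    rest = [c for c in out.columns if c not in _REPORT_LEAD]
    out = out[_REPORT_LEAD + rest]
    if fmt == "tsv":
        out.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        records = json.loads(out.to_json(orient="records"))
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
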