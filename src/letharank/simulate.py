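"""Self-consistent synthetic world with planted ground-truth suppressor genes.

The generator draws one latent per-cell-line resistance value and derives
from it (i) dose-response curves whose areas are a bounded monotone
transform of the latent resistance, (ii) planted genes whose expression and
dependency track resistance at a calibrated Pearson correlation, (iii) a
latent drug-response fold-change vector that every response profile is a
noisy copy of, and (iv) a knockdown-signature compendium in which the
planted genes' signatures mimic that response vector. Non-planted genes and
signatures are pure noise, so every downstream stage of the pipeline has a
testable planted signal and a calibrated null.

One master seed feeds a splittable RNG; each table draws from its own
stream, so regenerating one table never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import (
    FoldChangeProfile,
    GeneMatrix,
    SignatureCompendium,
    write_citations,
    write_gct,
    write_matrix,
    write_profiles,
)
from .vulnerability import DoseResponseFit, compute_auc, ll4

__all__ = ["WorldConfig", "WorldTruth", "SyntheticWorld", "generate_world", "world_to_files"]

#: citation-table vocabulary used by the generator
DEFAULT_TERMS = (
    "cell_death",
    "oxidative_stress",
    "iron_metabolism",
    "lipid_damage",
    "amino_acid_transport",
    "redox_enzyme",
)

#: dose grid shared by every simulated viability curve
DOSES = np.logspace(-2, 2, 8)


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults give a clearly recoverable signal."""

    n_genes: int = 500
    n_cell_lines: int = 16
    n_drugs: int = 3
    n_profiles: int = 10
    n_kd_genes: int = 100
    cell_lines_per_kd: tuple[int, int] = (4, 9)
    planted_suppressors: tuple[str, ...] | None = None  # None: ANCHOR1 + SUP01..SUP20
    planted_corr_strength: float = 0.7
    signature_mimic_strength: float = 0.8
    planted_cited_prob: float = 0.8
    background_cited_prob: float = 0.05
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_suppressors is None:
            self.planted_suppressors = ("ANCHOR1",) + tuple(
                f"SUP{i:02d}" for i in range(1, 21)
            )
        self.planted_suppressors = tuple(self.planted_suppressors)
        for name in ("n_genes", "n_cell_lines", "n_drugs", "n_profiles", "n_kd_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("planted_corr_strength", "signature_mimic_strength"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        lo, hi = self.cell_lines_per_kd
        if not (1 <= lo <= hi):
            raise ValueError("cell_lines_per_kd must be an increasing positive pair")
        if self.n_kd_genes < len(self.planted_suppressors):
            raise ValueError("n_kd_genes must cover all planted suppressors")
        if self.n_genes < self.n_kd_genes:
            raise ValueError("n_genes must cover the knockdown genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def anchor(self) -> str:
        return self.planted_suppressors[0]

    def gene_universe(self) -> list[str]:
        planted = list(self.planted_suppressors)
        n_bg = self.n_genes - len(planted)
        return planted + [f"G{i:05d}" for i in range(n_bg)]


@dataclass(frozen=True)
class WorldTruth:
    planted: tuple[str, ...]
    anchor: str


@dataclass
class SyntheticWorld:
    """Everything the pipeline consumes, plus the ground truth that seeded it."""

    config: WorldConfig
    viability: pd.DataFrame            # long: cell_line, drug, dose, viability
    auc: pd.DataFrame                  # cell_line x drug, noiseless analytic AUC
    expression: GeneMatrix
    dependency: GeneMatrix
    profiles: list[FoldChangeProfile]
    compendium: SignatureCompendium
    citations: pd.DataFrame            # genes x terms counts
    truth: WorldTruth


def _planted_vector(
    latent: np.ndarray, strength: float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """strength * latent + noise_sd * sqrt(1 - strength^2) * eps.

    At noise_sd = 0 the output is exactly collinear with the latent vector;
    at noise_sd = 1 the Pearson correlation with the latent is ~strength.
    """
    eps = rng.standard_normal(latent.shape)
    return strength * latent + noise_sd * np.sqrt(1.0 - strength ** 2) * eps


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a fully reproducible synthetic world from ``config.seed``."""
    genes = config.gene_universe()
    missing = [g for g in config.planted_suppressors if g not in genes]
    if missing:
        raise ValueError(f"planted genes absent from the universe: {missing}")
    planted = set(config.planted_suppressors)
    lines = [f"CL{i:02d}" for i in range(config.n_cell_lines)]
    drugs = [f"DRUG{i + 1}" for i in range(config.n_drugs)]

    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_latent, rng_viab, rng_expr, rng_dep, rng_prof, rng_sig, rng_cite = (
        np.random.default_rng(s) for s in streams
    )

    # (1) latent resistance and dose-response curves
    v = rng_latent.standard_normal(config.n_cell_lines)
    viab_rows = []
    auc = pd.DataFrame(index=pd.Index(lines, name="cell_line"),
                       columns=pd.Index(drugs, name="drug"), dtype=float)
    dose_range = (float(DOSES.min()), float(DOSES.max()))
    for li, line in enumerate(lines):
        for drug in drugs:
            e = 10.0 ** (0.6 * v[li] + 0.15 * rng_viab.standard_normal())
            fit = DoseResponseFit(b=1.2, c=0.0, d=100.0, e=e, rss=0.0, converged=True)
            auc.loc[line, drug] = compute_auc(fit, dose_range)
            clean = ll4(DOSES, 1.2, 0.0, 100.0, e)
            noisy = np.clip(
                clean + config.noise_sd * 2.0 * rng_viab.standard_normal(len(DOSES)),
                0.0, None,
            )
            for dose, viab in zip(DOSES, noisy):
                viab_rows.append((line, drug, dose, viab))
    viability = pd.DataFrame(viab_rows,
                             columns=["cell_line", "drug", "dose", "viability"])

    # (2) expression and dependency: planted genes track the latent resistance
    def planted_matrix(rng: np.random.Generator, scale_bg: float) -> GeneMatrix:
        values = np.empty((config.n_genes, config.n_cell_lines))
        for gi, gene in enumerate(genes):
            if gene in planted:
                values[gi] = _planted_vector(
                    v, config.planted_corr_strength, config.noise_sd, rng
                )
            else:
                values[gi] = scale_bg * rng.standard_normal(config.n_cell_lines)
        return GeneMatrix(pd.DataFrame(values, index=genes, columns=lines))

    expression = planted_matrix(rng_expr, 1.0)
    dependency = planted_matrix(rng_dep, 0.5)

    # (3) latent drug-response vector and the M noisy profiles (2 vs 2 replicates)
    f = rng_prof.standard_normal(config.n_genes)
    n_prof_lines = (config.n_profiles + 1) // 2
    line_effects = 0.5 * rng_prof.standard_normal((n_prof_lines, config.n_genes))
    profiles = []
    rep_sd = max(config.noise_sd * 0.5, 1e-6)
    for m in range(config.n_profiles):
        mean_t = f + line_effects[m // 2]
        treat = mean_t[:, None] + rep_sd * rng_prof.standard_normal((config.n_genes, 2))
        ctrl = rep_sd * rng_prof.standard_normal((config.n_genes, 2))
        log2fc = treat.mean(axis=1) - ctrl.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = sps.ttest_ind(treat, ctrl, axis=1, equal_var=True)
        pvals = np.nan_to_num(pvals, nan=1.0)
        pid = f"P{m // 2 + 1:02d}_{'A' if m % 2 == 0 else 'B'}"
        profiles.append(FoldChangeProfile(
            profile_id=pid,
            log2fc=pd.Series(log2fc, index=genes),
            p_value=pd.Series(pvals, index=genes),
        ))

    # (4) knockdown-signature compendium; planted signatures mimic f
    kd_genes = list(config.planted_suppressors)
    kd_genes += [g for g in genes if g not in planted][: config.n_kd_genes - len(kd_genes)]
    f_std = (f - f.mean()) / f.std()
    lo, hi = config.cell_lines_per_kd
    sig_cols, sig_ids, meta_rows = [], [], []
    mimic = config.signature_mimic_strength
    for gene in kd_genes:
        n_ctx = int(rng_sig.integers(lo, hi + 1))
        for ctx in range(n_ctx):
            eps = rng_sig.standard_normal(config.n_genes)
            if gene in planted:
                z = mimic * f_std + np.sqrt(1.0 - mimic ** 2) * eps
            else:
                z = eps
            sig_id = f"SIG_{gene}_{ctx}"
            sig_ids.append(sig_id)
            sig_cols.append(z)
            meta_rows.append((sig_id, gene, f"KDCL{ctx}", "trt_sh.cgs"))
    sig_df = pd.DataFrame(np.column_stack(sig_cols), index=genes, columns=sig_ids)
    meta = pd.DataFrame(
        meta_rows, columns=["signature_id", "perturbed_gene", "cell_line",
                            "perturbation_type"]
    ).set_index("signature_id")
    compendium = SignatureCompendium(matrix=GeneMatrix(sig_df), meta=meta)

    # (5) zero-inflated citation counts; planted genes are cited more often
    n_terms = len(DEFAULT_TERMS)
    cite = np.zeros((config.n_genes, n_terms), dtype=int)
    for gi, gene in enumerate(genes):
        prob = config.planted_cited_prob if gene in planted else config.background_cited_prob
        hits = rng_cite.random(n_terms) < prob
        counts = 1 + rng_cite.poisson(2, size=n_terms)
        cite[gi] = np.where(hits, counts, 0)
    citations = pd.DataFrame(cite, index=pd.Index(genes, name="gene"),
                             columns=list(DEFAULT_TERMS))

    return SyntheticWorld(
        config=config,
        viability=viability,
        auc=auc,
        expression=expression,
        dependency=dependency,
        profiles=profiles,
        compendium=compendium,
        citations=citations,
        truth=WorldTruth(planted=tuple(config.planted_suppressors),
                         anchor=config.anchor),
    )


def world_to_files(world: SyntheticWorld, outdir: str | Path) -> dict:
    """Write every world table in the formats the readers consume.

    Emits six data files plus a ``manifest.json`` recording paths, the seed
    and the planted truth. Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "viability": outdir / "viability.tsv",
        "expression": outdir / "expression.tsv",
        "dependency": outdir / "dependency.tsv",
        "profiles": outdir / "profiles.tsv",
        "signatures": outdir / "signatures.gct",
        "citations": outdir / "citations.tsv",
    }
    world.viability.to_csv(paths["viability"], sep="\t", index=False)
    write_matrix(world.expression, paths["expression"])
    write_matrix(world.dependency, paths["dependency"])
    write_profiles(world.profiles, paths["profiles"])
    write_gct(world.compendium, paths["signatures"])
    write_citations(world.citations.rename_axis("gene"), paths["citations"])
    manifest = {
        "seed": world.config.seed,
        "files": {k: str(v) for k, v in paths.items()},
        "truth": {"planted": list(world.truth.planted), "anchor": world.truth.anchor},
        "config": {
            k: (list(vv) if isinstance(vv, tuple) else vv)
            for k, vv in dataclasses.asdict(world.config).items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
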