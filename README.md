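# letharank

Rank candidate cell-death suppressor genes by integrating two evidence
streams:

1. **Correlation predictors** — fit four-parameter log-logistic dose-response
   curves per (cell line, drug), summarize each as a normalized AUC in
   log10-dose space (high = resistant), and Pearson-correlate every gene's
   expression and dependency values against the per-drug AUC vectors
   (2 modalities x 3 drugs = 6 predictors per gene).
2. **Similarity predictors** — score the top/bottom-20 gene sets of every
   knockdown signature in a compendium against each drug-response
   fold-change profile with a competitive enrichment test (variance inflated
   by a fixed inter-gene correlation), aggregate per knocked-down gene,
   and combine up/down ranks into a rank-difference score per retained
   profile. Profiles least similar to the consensus of all profiles are
   dropped first (default 3 of 10, leaving 7).

The 13 predictors are rank-normalized, embedded in 2-D with UMAP
(`min_dist = 0.05`), and genes are ranked by Euclidean distance to an anchor
gene known to suppress the death pathway. Supporting modules provide
pre-ranked GSEA / ssGSEA validation, embedding stability and fidelity
checks, offline citation-based validation of predictor combinations, and a
synthetic-world generator with planted ground-truth suppressors so the
entire pipeline is testable without any downloads.

## CLI

One executable with one subcommand per stage:

```bash
letharank simulate  --seed 1 --outdir world/           # synthetic world + manifest
letharank auc       --viability world/viability.tsv --outdir out/
letharank correlate --expression world/expression.tsv \
                    --dependency world/dependency.tsv --auc out/auc.tsv --outdir out/
letharank fin-rank  --profiles world/profiles.tsv --outdir out/
letharank select-predictors --profiles world/profiles.tsv --drop 3 --outdir out/
letharank similarity --gct world/signatures.gct --profiles world/profiles.tsv \
                     --retained out/retained_profiles.txt --outdir out/
letharank integrate --predictors out/correlation_predictors.tsv \
                    --similarity out/similarity.tsv --outdir out/
letharank neighbors --embedding out/embedding.tsv --anchor ANCHOR1 --k 75 --outdir out/
letharank enrich    --ranking ranking.tsv --gmt sets.gmt --outdir out/
letharank textmine  --citations world/citations.tsv \
                    --predictors out/correlation_predictors.tsv \
                    --similarity out/similarity.tsv --outdir out/
letharank run-all   --seed 1 --outdir out/             # simulate + every stage
```

Common flags: `--config config.yaml` (YAML mirroring `PipelineConfig`;
every CLI flag overrides it), `--seed`, `--outdir`, `--log-level`. The
effective configuration is logged to the output directory by `run-all`.

## File formats

TSV matrices (first column = gene id, header = sample ids), long-format TSV
fold-change tables (`profile_id, gene, log2fc, p_value`), GCT 1.2/1.3
signature compendia (1.3 column annotations `pert_iname` / `cell_id` /
`pert_type`, or a sibling `<file>.meta.tsv` for 1.2), GMT gene sets, and a
long TSV citation table (`gene, term, count`). All writers round-trip
losslessly through their paired readers for finite floats. No network I/O
anywhere.

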