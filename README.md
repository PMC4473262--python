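# crossomics

A tested, reusable pipeline for integrating blood metabolomics and
transcriptomics at population scale:

1. **synth** — synthetic cohorts with planted correlation modules, causal
   SNP chains, MCAR metabolite missingness, antagonistic HDL/TG-like
   traits, toy metabolic models and motif-hit tables, so every stage runs
   fully offline.
2. **preprocess** — missingness filtering (features with > 50% missing
   excluded), natural-log transform, per-feature age/sex OLS adjustment,
   probe-to-gene collapsing by maximum correlation strength.
3. **network** — all-pairs Spearman correlation on pairwise-complete
   samples, Benjamini–Hochberg thresholding (optionally over the full
   pre-collapse probe-level family), bipartite network construction,
   density diagnostics, replication in a second cohort, and blood-cell
   marker-list overlap.
4. **mr** — bidirectional Mendelian randomization per network edge:
   instrument validity screen (FDR) with LD pruning, Wald-ratio estimates,
   individual-level bootstrap CIs/p-values, BH q-values.
5. **metnet** — metabolic reconstruction handling (compartment merging,
   duplicate-reaction collapsing, currency-metabolite removal),
   metabolite–enzyme reaction-step distances on the undirected
   metabolite–reaction graph, and one-tailed Fisher enrichment of
   significant pairs by distance band.
6. **pin** — edge-constrained aggregated z-scores per functional-category
   pair and the Bonferroni-thresholded pathway interaction network.
7. **pheno** — per-feature/per-category trait regressions (HDL, LDL, TG)
   with signed −log10(p) node scores and cross-trait network comparison.
8. **regsig** — metabolite/pathway-derived gene sets, hypergeometric motif
   enrichment over a precomputed hit table, shared-TFBS matrices and
   metabolite–TF–target triad detection.

## CLI

Each stage is exposed as a subcommand of `crossomics`; all inputs and
outputs are plain text (TSV/JSON/GraphML):

```bash
crossomics simulate --seed 1 --out cohort/
crossomics preprocess --metabolome cohort/metabolome.tsv \
    --covariates cohort/covariates.tsv --out adjusted.tsv
crossomics correlate --metabolome adjusted.tsv \
    --transcriptome trans_adjusted.tsv --out corr.tsv
crossomics network --corr corr.tsv --fdr 0.01 \
    --out-graphml net.graphml --out-edges edges.tsv
crossomics distance --model cohort/model.json \
    --currency cohort/currency.txt --edges edges.tsv --out dist.tsv
crossomics pin --edges edges.tsv --metabolome adjusted.tsv \
    --transcriptome trans_adjusted.tsv --annotations cats.gmt \
    --out-pairs pairs.tsv --out-graphml pin.graphml
```

Run `crossomics --help` (or any subcommand with `--help`) for the full
option list, including `replicate`, `markers`, `mr`, `pheno` and `regsig`.

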