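# triomics

Integrated miRNA–mRNA–protein association analysis. Protein expression is
modeled as a power law in miRNA and in-cis mRNA expression (motivated by the
translation/degradation kinetics `P' = aE − bP`, whose fixation point is
`(a/b)·E`). The package provides:

- **`triomics.synthetic`** — seeded simulator for coupled miRNA/mRNA/protein
  cohorts with known coefficients (`protein = exp(α + Σ βⱼ·log Mⱼ + γ·log E + ε)`),
  optional subtype block structure, plus the kinetic ODE (closed form and a
  numerical integrator for cross-checking).
- **`triomics.preprocess`** — per-feature range standardization to
  `[δ₀, 1+δ₀]` (default δ₀ = 0.1) and natural-log transformation.
- **`triomics.univariate`** — the genome-scale screen: OLS of
  `log P = α + β·log M + γ·log E + ε` for every (protein, miRNA) pair, with
  the conservative estimator `FDR = N·P*/S` and threshold selection to hold
  the estimate under a target bound.
- **`triomics.multivariate`** — per-protein Lasso over all prescreened
  miRNAs (univariate p ≤ 0.01 by default), penalty chosen by k-fold
  cross-validation; intercept and γ unpenalized. The coordinate-descent
  solver supports per-coefficient penalty weights.
- **`triomics.interactome`** — Pearson-correlation-distance /
  complete-linkage two-way clustering of the coefficient table, fixed-k tree
  cutting (with a gap-statistic default), SIF edge-list export.
- **`triomics.scores`** — patient-specific miRNA-effect scores
  (Σ βⱼ·log Mⱼ per protein and patient), Euclidean/complete-linkage patient
  clustering, cluster-vs-clinical contingency tests, cross-cohort protein
  prediction, and overexpression-screen z-score consistency checks (|z| ≥ 1.96,
  matching sign).
- **`triomics.targets`** — overlap of negative significant associations with
  in-silico target-prediction lists (k-of-m voting).
- **`triomics.pipeline` / `triomics.cli`** — YAML-configured end-to-end run;
  all artifacts are TSV/JSON/SIF and a rerun with the same config is
  bit-identical (SHA-256 manifest in `summary.json`).

## CLI

```sh
# simulate a cohort with known ground truth
triomics simulate --n-samples 100 --n-proteins 20 --n-mirnas 60 \
    --support-size 3 --noise-sd 0.2 --seed 17 --outdir cohort/

# univariate screen (standardize + log + 20x60 OLS fits + FDR calls)
triomics fit-univariate --proteins cohort/protein.tsv --mrna cohort/mrna.tsv \
    --mirna cohort/mirna.tsv --gene-map cohort/gene_map.tsv \
    --fdr 0.01 --out univariate.tsv

# prescreen-constrained Lasso
triomics fit-multivariate --proteins cohort/protein.tsv --mrna cohort/mrna.tsv \
    --mirna cohort/mirna.tsv --gene-map cohort/gene_map.tsv \
    --table univariate.tsv --folds 10 --seed 0 --out-prefix mv

# or everything at once from a YAML config
triomics run --config run.yaml
```

Other subcommands: `standardize`, `cluster`, `export-network`, `scores`,
`predict`, `overlap`, `screen-validate`. All matrices are TSV with feature
rows, a sample-id header and a leading feature-id column.

A minimal `run.yaml`:

```yaml
proteins: cohort/protein.tsv
mrna: cohort/mrna.tsv
mirna: cohort/mirna.tsv
gene_map: cohort/gene_map.tsv
outdir: run1
target_fdr: 0.01
prescreen_alpha: 0.01
cv_folds: 10
cv_seed: 0
edge_threshold: 0.15
```

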