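# hybridgp

Metabolic-marker-assisted genomic prediction of hybrid performance.

`hybridgp` selects trait-associated metabolites from parental inbred lines
with a LASSO-path metabolome-wide association scan (MWAS), combines them
with genome-wide markers in a multi-kernel BLUP (REML variance components,
conditional-mean prediction) or a gradient-boosted-tree alternative,
evaluates five model configurations by repeated k-fold cross-validation,
and predicts and ranks every untested cross among the parents.

## Model configurations

| Tag     | Features                                                   |
|---------|------------------------------------------------------------|
| `GP`    | genome-wide markers only                                   |
| `MP`    | full metabolome (additive + dominance codings)             |
| `MMP`   | selected metabolic markers only                            |
| `M_GP`  | genome-wide markers + full metabolome                      |
| `MM_GP` | genome-wide markers + selected metabolic markers           |

Hybrid features are inferred from the parents: genotype = midparent code,
metabolite additive coding A = (M + F)/2, dominance coding D = |M − F|/2.

## Command line

```bash
hybridgp simulate --out data/ --seed 1 --n-parents 100 --n-hybrids 300
hybridgp qc --genotypes data/genotypes.tsv --metabolome data/metabolome.tsv --out qc/
hybridgp mwas --metabolome data/metabolome.tsv --phenotypes data/phenotypes_parents.tsv \
              --trait trait1 --out mwas.tsv
hybridgp run --config config.yaml      # qc -> mwas -> coding -> CV [-> all-cross prediction]
```

`config.yaml` mirrors the `PipelineConfig` schema (paths, QC thresholds,
MWAS alpha, model and engine lists, CV settings, seed). Exit codes:
0 success, 2 validation error, 1 runtime failure. Every run writes a
`manifest.json` listing inputs (with checksums), seeds, and all outputs.

## Library layout

- `data_io` — delimited/VCF/HapMap genotype readers, metabolome,
  phenotype and cross tables; SNP MAF/missingness filters; mean imputation.
- `metabolome_prep` — replicate-concordance filter (paired t-test),
  z-score normalization, replicate averaging, CV profiling.
- `mwas` — LASSO-path entry p-values (Gaussian level-crossing null with an
  exact correlation tail; permutation backend as oracle), marker selection,
  shared markers, marker correlations, per-metabolite genomic variance.
- `hybrid_coding` — midparent genotypes, A/D metabolite codings, feature
  assembly per model configuration.
- `gblup` — kernels K = WW'/q, multi-kernel REML (L-BFGS on
  log-variances, analytic gradients), block-partitioned BLUP prediction.
- `boosting` — histogram gradient boosting on [Z_G | A_M | D_M] with an
  in-repo TPE (tree-structured Parzen estimator) tuner minimizing
  inner-CV RMSE.
- `evaluation` — repeated k-fold CV (strict per-fold marker re-selection or
  fixed global list), predictive ability (squared Pearson correlation),
  paired model comparisons with compact letter display, random-metabolite
  control.
- `cross_prediction` — diallel enumeration, batched prediction of all
  crosses, top/bottom summaries and selection gains.
- `simulate` — fully seeded synthetic data: inbred parents, replicated
  metabolome partially under genetic control, sparse partial diallel,
  traits with additive + dominance + metabolite-mediated architecture,
  with ground truth recorded for recovery tests.

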