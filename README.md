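# famprs

Family-aware polygenic risk score (PRS) analysis, built as a reusable,
fully synthetic-testable pipeline:

* **PRS construction** from GWAS summary statistics at ten p-value
  thresholds, with positive-effect harmonisation, INFO filtering, relative
  risk-load scaling to [0, 1], and per-analysis Z-standardisation.
* **Cross-disorder weights**: a *shared* score from sign-concordant,
  nominally associated variants combined by DerSimonian–Laird
  random-effects meta-analysis, and *disorder-specific* summary statistics
  (conditional correction using LD-score-regression heritability and
  coheritability).
* **Kinship-aware association**: genomic relationship matrix on LD-pruned
  dosages, logistic mixed models (PQL with a simplex-optimised variance
  component) with one-sided Wald tests, and linear mixed models (REML) with
  cluster-bootstrap CIs and permutation p-values.
* **Null calibration**: ensembles of simulated scores matched in SNP count
  to the disorder score, tested with a fast fixed-covariance path, and
  summarised by an exact binomial success test with Clopper–Pearson CIs.
* **Synthetic cohorts**: multi-generation multiplex pedigrees under a
  correlated liability-threshold model with optional assortative mating,
  an unrelated case/control cohort, and matched training GWAS for three
  correlated disorders plus an uncorrelated negative control — so the whole
  pipeline runs with no external data.

## Command line

```sh
# synthetic cohort (genotypes, pedigree, phenotypes, training sumstats)
famprs simulate --seed 1 --out outdir

# harmonise + INFO-filter summary statistics
famprs harmonize --sumstats outdir/sumstats_BD.tsv --info-min 0.6 --out harmonised.tsv

# PRS at the default 10 thresholds
famprs score --sumstats harmonised.tsv --genotypes outdir/genotypes.tsv --out prs.tsv

# disorder-specific (conditional) summary statistics
famprs gwis --target bd.tsv --covariate mdd.tsv --h2-cov 0.3 --rho-g 0.1 --out bd_minus_mdd.tsv

# full pipeline: simulate -> weights -> scores -> mixed models -> calibration
famprs run-all --config config.yaml --seed 1 --out rundir
```

The YAML config has a `simulation:` section (cohort sizes, heritabilities,
prevalences, genetic correlations, assortative-mating strength) and a
`pipeline:` section (thresholds, score types, calibration ensemble size).

## Layout

```
src/famprs/
  simulate.py        synthetic cohorts, gene dropping, training GWAS
  sumstats.py        summary-statistics IO / harmonisation / alignment
  prs.py             thresholding, scoring, scaling, standardisation
  cross_disorder.py  shared meta-analysis, LDSC, conditional statistics
  mixed.py           GRM, logistic/linear mixed models, bootstrap, permutation
  calibration.py     simulated-score null and exact binomial test
  stats.py           descriptive tests and Bonferroni bookkeeping
  pipeline.py        end-to-end orchestration
  cli.py             famprs entry point
tests/               pytest suite (unit, property, acceptance)
scripts/acceptance.py
```
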