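# skinmgwas

A toolkit for genome-wide association analysis of skin-microbiome features,
covering the full chain from raw count tables to causal-inference follow-up:

- **Synthetic cohorts** (`skinmgwas.sim`): two-cohort, multi-site studies with
  Hardy-Weinberg genotypes (AR(1) Gaussian-copula LD blocks), adult covariates,
  hierarchical negative-binomial ASV counts with sequencing-depth offsets,
  confounder effects and planted SNP→taxon effects, plus two-sample MR summary
  statistics with a known causal effect — so every downstream stage is testable
  with known ground truth.
- **Feature construction** (`skinmgwas.features`): taxonomy aggregation,
  rarefaction, median>50 / prevalence>100 filters with the both-sites rule,
  Spearman ρ>0.985 redundancy clustering and Bray-Curtis dissimilarities.
- **Genotype QC** (`skinmgwas.qc`): exact conditional HWE test, MAF /
  missingness / biallelic / monomorphic filters with a per-rule removal log,
  and genetic principal components.
- **Association** (`skinmgwas.assoc`): the two-stage covariate-residualized
  framework. Univariate features: zero-truncated counts, 5×IQR outlier masking
  on rarefied counts, NB GLM (log-total offset, ML dispersion), Dunn-Smyth
  randomized-quantile residuals, per-SNP linear t-tests. Community
  composition: PCoA of the Gower-centered distance matrix, covariate
  projection, and a per-SNP pseudo-F whose p-value comes from a Pearson
  type III fit to the **exact** permutation moments of the statistic
  (`skinmgwas._moments`), with an explicit permutation fallback.
- **Meta-analysis** (`skinmgwas.meta`): inverse-variance and sample-size
  weighted fixed-effect combination, the genome-wide / nominal / dry-site
  decision rules, the study-wide threshold 5×10⁻⁸/80, and regression-method
  genomic inflation (λ_GC).
- **Fine-mapping** (`skinmgwas.finemap`): approximate Bayes factors, 95%
  credible sets under a single causal variant, and the LD r²>0.6 fallback.
- **Mendelian randomization** (`skinmgwas.mr`): instrument selection
  (p<10⁻⁵, greedy clumping, F≥10), allele harmonization with palindrome
  handling, Wald ratio / IVW / MR-Egger / weighted-median estimators, the
  supporting-evidence verdict and per-trait + global FDR.
- **Orchestration** (`skinmgwas.pipeline`, `skinmgwas.io`): plain-text TSV/VCF
  readers and writers with dialect headers, and an end-to-end pipeline with
  digest-based stage caching.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, one test per
criterion. One criterion (the λ_GC ≤ 1.02 bound on a 5,000-SNP null cohort) is
statistically fragile at desk scale — the regression estimator itself has null
sampling sd ≈ 0.024 at m = 5,000, so the maximum over 10 features exceeds the
bound for most seeds even though the test is exactly calibrated (mean λ ≈
1.000). It is left as-is rather than loosened; see the test docstring.

## CLI

The `mgwas` umbrella command exposes one subcommand per stage:

```bash
mgwas simulate --seed 1 --out runs/sim
mgwas qc --genotypes runs/sim/geno_cohortA.x --maf 0.05 --hwe 1e-5 --out runs/qc
mgwas features --counts siteA=runs/sim/abund_X.x --counts siteB=runs/sim/abund_Y.x \
    --microenv moist --out runs/features_moist.tsv
mgwas assoc --genotypes runs/qc/geno_qc.x --abundance runs/sim/abund_X.x \
    --covariates runs/sim/covariates_cohortA.tsv --pcs runs/qc/pcs.tsv \
    --feature-list runs/features_moist.tsv --site siteA --out runs/assoc_siteA.tsv
mgwas meta --sites runs/assoc_siteA.tsv runs/assoc_siteB.tsv --microenv moist \
    --out runs/meta_moist.tsv
mgwas finemap --meta runs/meta_moist.tsv --genotypes runs/qc/geno_qc.x --w 0.04 \
    --out runs/finemap.tsv
mgwas mr --exposures runs/exposures/ --outcomes runs/outcomes/ --out runs/mr.tsv
```

or run everything on a synthetic study from a YAML config:

```bash
mgwas run --config config.yaml --out runs/full
```

Re-running skips stages whose input digests are unchanged; corrupting an
intermediate file reruns only the downstream stages.

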