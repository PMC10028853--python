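# regdiff

Gene-level testing of whether the **cis-genetic regulation of expression
differs between two biological contexts** (tissues, cell types, disease
states). For each gene, context-specific elastic-net models are trained to
predict expression from nearby variant dosages, and a bootstrap
model-comparison test asks whether the two *population-level* models have
equal predictive performance — accounting for the variability of feature
selection and model training, which a naive paired t-test on prediction
errors ignores.

## Method outline

1. **Preprocessing.** Samples are split into two equal training sets (A, B)
   and a disjoint test set. Per gene, variants within ±500 kb of the
   transcribed region are extracted; expression and dosages are residualized
   on user covariates *separately within each split*, standardized, and
   monomorphic sites are removed (harmonized across splits).
2. **Model training.** Gaussian elastic net (mixing weight α = 0.5) with a
   100-point log-spaced penalty grid, 5-fold cross validation and the
   one-standard-error rule.
3. **Testing.** The mean difference in squared prediction error on the test
   set is compared against a denominator that adds (a) the usual paired-t
   variance of the mean and (b) the variance of the statistic across K
   bootstrap retrainings of both models (resampling each training set with
   replacement and rerunning the full fit, penalty search included). The
   statistic is referred to Student's t with |test set| − 1 degrees of
   freedom. A conditional paired t-test on the same loss differences is
   reported alongside for comparison.

Variant QC (autosomes, ACGT allele codes, no missing calls, exact HWE mid-p
≥ 1e-6, MAF ≥ 0.01) is applied before anything else.

### A note on calibration

Rerunning the cross-validated penalty search inside every bootstrap
replicate (the default, and the procedure the method describes) makes the
bootstrap variance term systematically *over*-estimate the true
training-set variability of the statistic, so the test is distinctly
conservative under the null in clean simulations (genomic-control lambda
roughly 0.3–0.7 across a wide range of synthetic architectures). Freezing
the penalties at their full-sample values inside replicates
(`--freeze-lambda`, or `RunConfig(reselect_lambda=False)`) removes the
penalty-tuning variance and lands near — typically slightly above — nominal
calibration. The default stays with the faithful procedure; choose per your
false-positive tolerance.

## CLI

```sh
# generate a synthetic, immediately runnable input set
regdiff simulate --out sim/ --kind null --n 300 --p 50 --genes 10 --seed 1

# run the per-gene tests
regdiff run \
  --bfile sim/geno --expr-a sim/expr_a.tsv --expr-b sim/expr_b.tsv \
  --covar sim/covar.tsv --annot sim/annot.tsv --genes sim/genes.txt \
  --out results/ --test-context A --split thirds --boot-k 50 --seed 1

# calibration diagnostics (genomic lambda, QQ table, Bonferroni counts)
regdiff diagnose --results results/results.tsv --out diag/
```

Inputs: PLINK 1 BED/BIM/FAM genotypes; TSV expression matrices
(genes × samples) per context; optional TSV covariates (samples × columns);
TSV gene annotation (`gene_id  chrom  tss  tes`, 1-based inclusive); a
plain-text gene list. `--test-context {A|B}` selects whose measured
expression forms the test-set response (required; the choice affects power,
not type-I error). Output `results.tsv` has one row per gene:
`gene_id  n_train  n_test  delta_loss  t_boot  df  p_boot  t_cond  p_cond
n_snps_selected_a  n_snps_selected_b  status`.

Dosages count copies of the BIM allele1; orientation does not affect any
statistic (columns are standardized) but is fixed for reproducibility.

## Package layout

| module | contents |
| --- | --- |
| `regdiff.io_formats` | PLINK BED/BIM/FAM codec, TSV readers/writers, core data types |
| `regdiff.qc_variants` | MAF, exact Levene–Haldane HWE mid-p, variant filters |
| `regdiff.preprocess` | splits, cis-window extraction, residualization, standardization |
| `regdiff.enet` | elastic-net path, CV, one-SE penalty selection |
| `regdiff.boottest` | conditional paired t-test and the bootstrap comparison test |
| `regdiff.runner` | per-gene orchestration, CLI, Bonferroni/lambda/QQ diagnostics |
| `regdiff.simulate` | synthetic genotype/expression cohorts with truth labels |
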