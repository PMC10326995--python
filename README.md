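# iqtl

Interaction molecular-QTL mapping toolkit: cis G×E interaction scans for
molecular phenotypes (expression / methylation), hierarchical
multiple-testing correction, direction-of-effect classification,
sentinel collapsing of CpG records, reproducibility / sharing /
replication statistics, mediated-moderation analysis, and a synthetic
cohort generator so the whole pipeline is testable without restricted
cohort data.

## What it does

- **`iqtl.iqtl_scan`** — fits `Y ~ G + E + G×E + C` by OLS for every cis
  phenotype–variant pair (±1 Mb of a gene TSS or ±500 kb of a CpG site)
  using a batched normal-equations implementation, after a global MAF
  filter (> 0.01) and an interaction-aware filter requiring MAF above a
  threshold in *both* halves of the interaction variable's distribution.
- **`iqtl.significance`** — per-phenotype effective-number-of-tests
  correction (eigendecomposition of the local genotype correlation in
  windows of 200, 99% variance), Benjamini–Hochberg across phenotypes,
  and cross-exam combination of significant calls.
- **`iqtl.direction`** — three-category direction calls for continuous
  interaction variables (sign of `b_g · b_gxe` given a significant main
  effect) and four-category calls for binary variables from per-group fits.
- **`iqtl.preprocess`** — rank-based inverse normal transform with
  tie-breaking noise (N(0, 1e-16)), ±k·SD outlier masks, mean-centering,
  the two-half MAF filter, and greedy ±1 kb sentinel collapsing.
- **`iqtl.concordance_stats`** — fixed-λ Storey π0/π1 with the
  sample-size-dependent λ rule, nominal replication rates, inflation λ
  (median χ²₁ ratio), LD r², normalized overlap with a min-denominator,
  Haldane–Anscombe-corrected odds ratios, allelic concordance, median
  absolute effects.
- **`iqtl.mediation`** — mediated moderation (does a G×cell interaction
  carry an apparent G×age effect?) via two OLS models, product-of-
  coefficients ACME/ADE, nonparametric bootstrap with BCa intervals and
  bootstrap p-values, plus a λ-based enrichment screen.
- **`iqtl.synthetic_data`** — seeded generators for HWE dosages with
  AR(1) linkage, simplex cell proportions with a target age correlation,
  and phenotypes under null / G×cell / direct G×trait / mediated /
  binary-exposure scenarios, with a ground-truth table.
- **`iqtl.io_formats`** — tensorQTL-style phenotype BED, VCF (GT/DS via
  cyvcf2) or dosage TSV, covariate/interaction TSVs, results TSVs with a
  stable column order; one-time sample alignment into a `DatasetBundle`.

## CLI

```bash
iqtl simulate --scenario gxcell --n 800 --phenotypes 200 --seed 1 --out data/
iqtl scan --bed data/phenotypes.bed --dosages data/genotypes.tsv \
    --covariates data/covariates.tsv --interactions data/interactions.tsv \
    --interaction neutrophil --window gene --out results/run
iqtl direction --results results/run.top.tsv --out results/run.dir.tsv
iqtl sentinel --results results/run.dir.tsv --window-bp 1000 --out results/run.sent.tsv
iqtl stats pi1 --results results/validation.tsv --out results/pi1.tsv
iqtl stats lambda --results results/run.pairs.tsv --out results/lambda.tsv
iqtl mediate --bed data/phenotypes.bed --dosages data/genotypes.tsv \
    --covariates data/covariates.tsv --interactions data/interactions.tsv \
    --phenotype phen_0000 --variant var_1_2099993 \
    --moderator age --mediator neutrophil --n-boot 1000 --seed 1 --out results/med.tsv
```

Subcommands accept `--config FILE` with `key=value` overrides
(`maf_global=0.01`, `maf_interaction=0.05` or `0.1` for trait scans,
`sentinel_window_bp=1000`, `fdr=0.05` or `0.25`, ...).

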