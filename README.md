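# ecgherit

Pedigree-based heritability analysis of electrocardiogram (ECG) traits, and
of how much of that heritability known GWAS variants explain — including
cross-phenotype (pleiotropic) effects.

The package is aimed at genetic epidemiologists working with extended family
cohorts. It covers the full chain from a PLINK-style pedigree file to a
per-trait heritability decomposition table:

* recursive kinship matrices Φ and inbreeding coefficients *F* from pedigree
  structure, with the inbreeding quartile classification used in
  consanguineous cohorts;
* construction of the analysis traits from raw ECG measurements — QRS
  duration, Bazett-corrected QT (QTc = QT/√RR), PR interval, and the three
  voltage-duration left-ventricular-hypertrophy (LVH) proxies
  (Sokolow–Lyon, Cornell, 12-lead sum), with the standard per-trait
  exclusion rules (clinical flags, QRS > 120 ms, PR ≥ 320 or ≤ 80 ms,
  QRS axis > 90° or < −30°);
* covariate residualization (sex, age, BMI, height, heart rate — heart rate
  omitted for QTc) followed by rank-based inverse-normal transformation;
* maximum-likelihood polygenic variance-component estimation of
  narrow-sense heritability, h² = σ²g/(σ²g + σ²e), under
  y = Xβ + g + e,  g ~ N(0, 2Φσ²g),  e ~ N(0, Iσ²e),
  via a one-time eigendecomposition of 2Φ and a 1-D profile-likelihood
  search, with REML available for bias-free conditioning comparisons;
* the three-model SNP-conditioning procedure: model 1 (covariates only),
  model 2 (+ trait-specific GWAS SNP dosages), model 3 (+ all ECG GWAS
  SNPs), with Δh², the proportion of heritability explained
  (100·Δh²/h²₁), boundary likelihood-ratio tests of h² = 0
  (½χ²₀ + ½χ²₁ null), nested LRTs between models, and a per-SNP-set
  cross-phenotype decomposition;
* a gene-dropping family simulator that generates complete synthetic
  cohorts (pedigree, dosages, phenotypes, raw ECG columns, SNP catalog)
  with exactly known variance composition, so the whole pipeline is
  testable end to end without access to individual-level data.

## Worked example

Simulate a PR-interval-like family cohort (polygenic variance 0.368,
9 PR SNPs carrying 0.008 of the variance, cross-trait SNP sets carrying
0.024, residual 0.60) and run the three-model decomposition:

```sh
ecgherit simulate --preset pr --seed 42 --out demo
ecgherit explain --trait PR --pedigree demo/ped.fam --phenotypes demo/pheno.tsv \
    --dosages demo/dosages.tsv --catalog demo/catalog.tsv --out demo/report
```

which logs

```
INFO ecgherit.preprocess: pipeline PR: exclusions -> derived -> residualize -> rank INT (n=973 kept, 31 dropped)
INFO ecgherit: model 1: loglik=-1336.61 h2_total=0.437 (0 SNPs)
INFO ecgherit: model 2: loglik=-1347.48 h2_total=0.434 (9 SNPs)
INFO ecgherit: model 3: loglik=-1420.42 h2_total=0.403 (68 SNPs)
```

and writes `demo/report/heritability.{tsv,json}`. In this run the
unconditioned PR heritability is 0.437; conditioning on the 9 PR SNPs
leaves 0.434 (0.5 % of the heritability explained), and adding the
59 SNPs discovered for the other ECG traits drops it to 0.403 — a further
7.2 % explained, 4.8 points of which come from the QRS SNP set alone
(`cross_QRS_additional_pct` in the report). A single cohort is one draw:
replicate-level Δh² has a standard deviation of ~0.01–0.03 at this sample
size, so Δh² can come out slightly negative for weak SNP sets; the pipeline
reports such values as-is rather than clamping them.

The same analysis is available from Python:

```python
from ecgherit import (simulate_ecg_cohort, trait_preset, select_index_snps,
                      run_three_models)

bundle = simulate_ecg_cohort(trait_preset("pr", seed=42))
catalog = select_index_snps(bundle.catalog)
report = run_three_models("PR", ..., bundle.dosages, catalog, bundle.kinship)
```

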