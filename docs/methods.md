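# Methods

## The polygenic variance-component model

For a quantitative trait y measured on n members of a known pedigree,

    y = X beta + g + e,   g ~ N(0, 2 Phi sigma2_g),   e ~ N(0, I sigma2_e),

where Phi is the kinship matrix: Phi_ij is the probability that a random
allele drawn from i and one drawn from j are identical by descent, so the
additive genetic covariance between relatives is 2 Phi_ij sigma2_g and the
diagonal of 2 Phi is 1 + F_i, with F_i the inbreeding coefficient (the
kinship of i's parents). Narrow-sense heritability is
h2 = sigma2_g / (sigma2_g + sigma2_e): the fraction of (covariate-adjusted)
phenotypic variance attributable to additive genetic effects.

Kinship is computed exactly by the recursive method in topological order
(founders: Phi_ii = 1/2, unrelated; non-founders: Phi_ii = (1 + Phi_fm)/2,
Phi_ij = (Phi_fj + Phi_mj)/2). Monte-Carlo gene dropping would also work but
is approximate; the recursion is O(n^2) and exact, and a gene-dropping
estimator survives in the test suite as an independent oracle. Individuals
with zero F form their own class; positive F values are split at their
25/50/75th percentiles (boundary ties to the lower class — the usual
quartile scheme for a heavily right-skewed F distribution). The package
keeps a single convention: `pedigree` reports Phi, and the doubling to the
additive relationship 2 Phi happens once, inside `varcomp`.

## Fitting

V = 2 Phi sigma2_g + I sigma2_e is diagonalized once per cohort:
2 Phi = U D U'. Rotating y and X by U' makes V diagonal with entries
sigma2_p (h2 d_i + 1 - h2), after which beta (by weighted least squares) and
the scale sigma2_p profile out analytically and only h2 in [0, 1] remains,
optimized by bounded scalar search (tolerance 1e-8 on h2), with the
endpoints checked explicitly so boundary optima (h2 = 0 or 1) are exact.
The rotated likelihood is tested against direct dense multivariate-normal
evaluation to 1e-8. Degenerate fixed-effect designs are reduced to a
full-column-rank basis first (dropped columns get beta = 0), which keeps
the REML determinant finite and the likelihood well defined.

Degenerate inputs: a relatedness matrix numerically proportional to the
identity makes sigma2_g and sigma2_e jointly unidentifiable and raises an
error rather than returning an arbitrary split; eigenvalues of 2 Phi below
-1e-8 fail a positive-semidefiniteness check; tiny negative eigenvalues are
clipped to zero.

Standard errors come from the delta method on the numerically
differentiated observed information of (sigma2_g, sigma2_e) (central
differences, step 1e-5 x parameter scale). At a boundary estimate the SE is
reported as NaN with a warning — the quadratic approximation is meaningless
there.

### ML, REML, and the two heritability scales

`fit_polygenic` defaults to maximum likelihood, and every likelihood-ratio
test is computed from ML fits:

* h2 = 0 sits on the parameter boundary, so the LRT statistic is referred
  to the 50:50 mixture of a point mass at zero and chi-square(1)
  (p = 0.5 P(chi2_1 > Lambda)). On sibship designs of a few hundred
  individuals the empirical type-I error is 4-5% at nominal 5%; very
  shallow pedigrees make the test conservative (little variance-component
  information), which the calibration test documents.
* Nested fixed-effect comparisons (model 1 vs 2 vs 3) use chi-square with
  df = number of added (linearly independent) SNP columns. REML
  log-likelihoods are not comparable across fixed-effect sets, so these
  tests always refit by ML even when point estimates use REML — the same
  convention lme4 users follow.

The *reported* variance components in the conditioning pipeline use REML.
The reason is specific and measurable: gene-dropped SNP dosage columns
carry the same family covariance structure as the polygenic effect, so an
ML fit that conditions on p such columns spends degrees of freedom
concentrated exactly in the high-kinship eigendirections where g lives,
deflating sigma2_g-hat by ~0.03 at p = 21, n = 1400 even when the SNPs have
no effect at all. REML integrates beta out and removes this bias; with it,
conditioning on null SNPs changes the heritability estimate by < 0.005.

Two heritability scales are exposed on every fit:

* `h2` — sigma2_g / (sigma2_g + sigma2_e), heritability of the variance
  left after fixed effects;
* `h2_total` — sigma2_g / (sigma2_g + sigma2_e + var_fixed), heritability
  against the total phenotypic variance including the variance captured by
  non-intercept fixed effects.

Model comparisons use `h2_total`: it keeps the denominator constant across
models 1-3, which is what makes "Delta h2" and "proportion of heritability
explained by SNPs" (100 (h2_1 - h2_2)/h2_1) interpretable — on the `h2`
scale, removing SNP variance from the denominator would understate the
drop. var_fixed is the sample variance of X beta-hat minus its estimation-
noise expectation tr(Xc' Xc Cov(beta-hat))/n; without that subtraction,
36 null SNP columns at n = 1500 would fake ~2.4 points of "explained"
variance. Delta h2 may legitimately come out negative (conditioning can
nudge the estimate upward); the pipeline reports it as-is.

## Trait construction

Raw ECG measurements are taken as inputs (signal delineation is upstream).
QTc uses Bazett's formula QT/sqrt(RR), RR = 60/HR in seconds. The LVH
proxies are voltage-duration products in mm*ms: Sokolow-Lyon
(S_V1 + max(R_V5, R_V6)) x QRS, Cornell (R_aVL + S_V3) x QRS, and the
12-lead sum over all leads x QRS. "R wave in V5 or V6" is read as the
maximum of the two (the standard convention). The 12-lead sum reads "R-S"
as total QRS amplitude |R| + |S| per lead — the reading consistent with a
voltage-product index; a signed R - S mode is selectable for sensitivity
analyses. Exclusions: the clinical flags (atrial fibrillation, myocardial
infarction, bundle-branch block, AV block, pacemaker, WPW, pregnancy,
class I/III antiarrhythmics or digoxin) apply to every trait; QRS > 120 ms
to QRS/QT and the LVH proxies; PR >= 320 or <= 80 ms (boundaries excluded
inclusively, as printed) to PR only; axis > 90 or < -30 degrees to the LVH
proxies only.

Covariates are residualized once, before the variance-component models,
and the models then carry only an intercept (model 1) plus SNP dosages
(models 2-3). Adjusting both before and inside the models would
double-count; adjusting only inside would force every model refit to carry
five extra columns for no benefit. The rank-based inverse-normal transform
uses average ranks for ties and the Blom offset, Phi^-1((r - 3/8)/(n + 1/4));
the choice of offset is immaterial beyond two decimals at n ~ 1500 but is
fixed for determinism. Missing data are handled complete-case per trait,
and all three models of a trait are refit on the identical complete-case
subset (individuals are dropped, never SNPs) so log-likelihoods remain
comparable.

Model 2's "trait-specific" SNP set is the trait's own genome-wide-
significant set for QRS, QT and PR. The LVH proxies have essentially no
hits of their own, but QRS duration is a multiplicative component of all
three, so their model 2 carries the QRS set (12LS additionally its own two
SNPs). Catalog handling keeps one index SNP per locus (lowest discovery P,
ties broken by id) and logs SNPs unavailable in the dosage data.

## The synthetic cohort generator

The generator emulates a genetically isolated founder population: a founder
pool (default 50) followed by six generations in which each adult
reproduces with probability 0.65, finds a mate inside the population with
probability 0.5 (otherwise a spouse "marries in" as a new founder), and
in-population matings are preferentially between first cousins with
probability 0.15. These defaults yield cohorts around 1500 individuals
whose nonzero pairwise kinship has median ~0.004 and whose inbreeding
distribution is right-skewed with a point mass at zero — the structure of
the target study population. The branching process has a heavy-tailed size
distribution, so recovery experiments redraw until the realized size lands
in [1350, 1650].

Phenotypes are y = covariates + sum_s D_s b_s + g + e: g is drawn through
the eigendecomposition square root of 2 Phi (exact, rather than gene-
dropping thousands of loci; an infinitesimal gene-dropped mode is
deliberately out of scope), e is i.i.d. normal, and each SNP set's
contribution uses gene-dropped dosages (founder alleles Bernoulli(maf),
Mendelian transmission). Every component is rescaled so its *realized*
sample variance equals its configured fraction exactly — recovery targets
then have tight tolerances at a single cohort size, at the cost of
slightly shrinking replicate-to-replicate variance relative to nature.

Trait presets fix the variance compositions implied by the published
estimates (e.g. QRS: polygenic 0.28 + own-SNP set 0.06 + residual 0.66;
PR: polygenic 0.368 + PR set 0.008 + QRS set 0.020 + QT set 0.002 + 12LS
set 0.002 + residual 0.60). The full cohort bundle additionally back-solves
raw ECG columns (intervals, lead amplitudes, covariates, ~2-4% exclusion-
flagged records) so that the derived traits reproduce the simulated ones;
for the 12-lead sum the remaining-lead amplitudes are floored at zero, so
in the ~1% of records where the Sokolow-Lyon/Cornell-fixed leads already
exceed the 12LS target the product is floored rather than made negative.

What the generator does **not** emulate: linkage disequilibrium between
catalog SNPs, assortative mating, shared-household environmental
covariance, genotyping/imputation error, non-Gaussian trait scales beyond
what the rank transform removes, and cross-trait phenotypic correlations
(each trait's polygenic draw is independent). Passing recovery tests
therefore demonstrate estimator correctness under the stated model, not
robustness to those real-data features.

## Recovery experiments and problem sizes

`ecgherit.recovery` runs the study-scale experiments: one ~1500-person
pedigree per scenario (one eigendecomposition, reused), 50 replicate
genotype+phenotype redraws, per-replicate model fits, replicate-mean
summaries. With the analytic profile likelihood each replicate costs one
O(n^2) rotation plus a 1-D search, so a full 10-scenario acceptance run
completes in ~30 s on one CPU. The boundary-LRT calibration uses a
30-family x 6-sib design (n = 240) and 1000 replicates.

## Known limitations

* Household/shared-environment variance is not modeled (additive +
  residual only, matching the h2 definition used); where such variance
  exists in real data it inflates h2.
* The SE of h2 is information-based; profile-likelihood intervals would be
  asymmetric near boundaries.
* X-linked and dominance relatedness matrices are out of scope, as is
  marker-based (GRM) relatedness.
* The boundary LRT is conservative on small shallow pedigrees.
* Dosage input is TSV only (no VCF/PLINK-binary parsing in this version).
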