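# Methods

## Model and estimand

The response is systolic blood pressure, log-transformed to control
skewness and standardized to zero mean and unit sample variance
(ddof = 1).  The working model is a linear mixed-effects regression

    y_i = mu + Z_i' gamma + x_i' beta + eps_i,   eps_i ~ iid N(0, sigma_eps^2)

with flat priors on the intercept and the four covariate effects (age
in years, sex, smoking and blood-pressure medication, all taken from
the same visit as the SBP value), iid N(0, sigma_beta^2) priors on the
marker effects, and independent scaled-inverse-chi-square priors on
sigma_beta^2 and sigma_eps^2.  Marker dosages are centered at twice the
coded-allele (unfolded) frequency; missing dosages are imputed at the
column mean, i.e. zero after centering.  Residuals are iid: family
structure is deliberately not modelled (the simulator can induce
relatedness by gene-dropping, but the fitted likelihood ignores it —
a known source of inflation on family data).

The estimand is the proportion of phenotypic variance explained by a
model m, R^2_m = 1 − sigma_eps^2-hat(m), with sigma_eps^2-hat the
posterior mean (optionally median) of the residual-variance chain.
Because y has unit variance this is an R-squared; it is a marker-based
quantity, bounded above by heritability, since markers capture causal
variance only through linkage disequilibrium.

## Gibbs sampler

All full conditionals are conjugate:

* (mu, gamma): scalar-wise normal conditionals with flat priors,
  updated with incremental residual bookkeeping (no per-iteration
  matrix inversion);
* beta_l ~ N(c_l x_l'e_l, sigma_eps^2 c_l), c_l = 1/(x_l'x_l +
  sigma_eps^2/sigma_beta^2), where e_l restores marker l's own
  contribution to the residual;
* sigma_beta^2 ~ scaled-inv-chi2(df_b + L, (sum beta^2 + df_b s_b)/(df_b + L));
* sigma_eps^2 ~ scaled-inv-chi2(df_e + n, (e'e + df_e s_e)/(df_e + n)).

The marker sweep is sequential and is compiled with numba; the normal
deviates it consumes are drawn beforehand from a single
`numpy.random.Generator`, so a chain is bit-reproducible from its seed.
The residual is recomputed from scratch every 512 iterations to cap
incremental floating-point drift.  Defaults follow the headline
analysis settings: 40,000 iterations, 15,000 burn-in, thinning 1
(25,000 kept samples).  Convergence is monitored numerically —
effective sample size and split-chain rank-normalized R-hat on the
scalar chains (arviz) — alongside optional PNG trace plots; scalar
chains are stored in full while marker effects keep only a running
posterior mean unless `store_beta=True` (memory).

Priors default to df = 5 on both variances, with scales set by a
variance-partition rule (`partition_r2`, default 0.5): the prior mode
of sigma_eps^2 equals (1 − partition_r2)·Var(y), and scale_beta is
solved so the implied prior marker variance sum_l var(x_l)·E[sigma_beta^2]
equals partition_r2·Var(y).  This is proper and mildly informative, the
standard practice in whole-genome regression; the exact hyperparameters
behind the original analysis are not recoverable, only "weakly
informative" is specified.

## Variant classification

QC keeps variants flagged as passing with exactly two alleles.  Folded
MAF = min(f, 1−f) over non-missing calls.  Bins: very rare (MAF < 1%),
rare (1% ≤ MAF ≤ 5%), common (MAF > 5%); the source description of the
rare bin is an evident typo ("1% ≥ MAF ≥ 5%") and both boundaries are
assigned to rare, consistent with the strict inequalities of the
neighbouring bins.  A variant is genic if its position lies inside a
gene's transcribed interval (0-based half-open intervals; variant
positions 1-based), flanking if within ±50 kb outside one, otherwise
outside; genic takes precedence, each variant is counted once however
many genes it flanks, and flanks are measured from the interval bounds
without strand awareness.  Monomorphic variants (MAF = 0) fall in
very_rare and are retained by default (they contribute nothing after
centering); `drop_monomorphic` removes them.  Marker sets are the
{all, genic, flanking} × {all, common, rare, very_rare} grid with
"outside" variants excluded throughout.

## Fixed-size resampling

Set-level R^2 confounds the nature of a set with its size.  The
comparison therefore refits each category on a fixed number of markers
(default 500) drawn at random *without* replacement — with-replacement
draws would duplicate columns and corrupt the x_l'x_l conditioning —
repeated 500 times, reporting mean ± SD (ddof = 1) over replicate R^2.
Replicate sub-seeds are derived from the master seed by a counter-keyed
`SeedSequence`, so replicates are reproducible and order-independent.
Per-replicate chains default to 5,000 iterations / 1,000 burn-in: the
full headline settings across 500 replicates × 12 sets are
cluster-scale, and the shorter chains change replicate R^2 well within
the across-replicate SD; full settings remain configurable.

## Synthetic data

The generator emulates the structure the analysis assumes, with
defaults fixed at the study conditions: 395 subjects; a 31-gene panel
(20 kb genes, one per slot of an 8 Mb chromosome, jittered so genic
±50 kb footprints never overlap); 49,839 variants at the observed MAF
mixture (64% very rare, 13% rare, 23% common) and a 34/66 genic/flank
split; true frequencies drawn uniformly inside boundary-safe ranges
(0.001–0.009, 0.012–0.048, 0.06–0.45) so the generating bin is
recoverable; Hardy-Weinberg iid genotypes, or gene-dropped nuclear
families (2 founders + k children) when relatedness is wanted.  Class
counts are allocated deterministically (round, remainder to the largest
class), making composition tests exact.

Phenotypes follow the generative twin of the fitted model: logSBP =
mu + Z gamma + Xc beta + eps, exponentiated to SBP, re-observed at 4
visits with log-scale measurement noise (sd 0.05) and per-visit
missingness (default 10%).  Covariates: age U(30, 70), sex/smoking/
medication Bernoulli(0.5/0.2/0.3) — no empirical distributions are
available, these are plausible cohort values.  Effects: 500 causal
markers with beta ~ N(0, sigma_b^2), sigma_b^2 solved from the realized
centered-column variances so the expected marker variance share equals
`h2_markers` (default 0.3, large enough to be detectable at n = 395);
covariate effects (0.04, 0.6, 0.5, 0.4) give a covariate share of
~0.19, matching the covariates-only R^2 scale of the motivating
analysis; residual sd 1 on the log scale before standardization.

What the generator does **not** emulate: linkage disequilibrium beyond
what gene-dropping induces, sequencing error, genotype imputation
uncertainty, real pedigree topologies, secular trends across visits.
Passing tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to the LD
structure or relatedness of real sequence data.

## Numerical choices and degenerate inputs

Sample SD uses ddof = 1 throughout.  Standardization centers as well as
scales (harmless given the intercept, and it makes R^2 exact).
Monomorphic (zero-variance) marker columns are legal: their centered
column is zero, x_l'x_l = 0, and the conditional degenerates gracefully
to the prior.  L = 0 (covariates-only) skips the beta and sigma_beta^2
updates.  All-missing genotype columns, non-positive SBP, fewer than
two subjects, subset draws larger than the set, and infeasible gene
packing raise explicit errors.  MAF outside [0, 0.5] is rejected rather
than folded silently.

## Problem sizes in the shipped tests and acceptance script

The full study scale (≈50k variants × 25,000 kept samples × 13 sets,
plus 500 × 500 resampling fits) is a cluster workload.  The shipped
test suite and `scripts/acceptance.py` exercise the identical code
paths at reduced sizes chosen as this package's own verification
budget: hundreds to 3,000 variants, chains of 2,000–6,000 iterations,
resampling at 20 replicates of 500 markers.  Sampler correctness is
established at these sizes by exact oracles (OLS for the
covariates-only posterior mean, the ridge/mixed-model-equations
solution with clamped variances, Kolmogorov–Smirnov tests of every
conjugate conditional against its analytic density), and parameter
recovery by simulating at n = 400 with a known 0.3 marker share and
checking R^2_full − R^2_cov against it across seeds.

## Known limitations

* iid residuals on family-structured data overstate the precision of
  R^2; no pedigree or genomic-relationship random effect is offered.
* R^2 = 1 − sigma_eps^2-hat is a shrinkage-model summary, not an
  unbiased variance-component estimate; with few subjects and many
  markers it carries the prior's imprint (the `partition_r2 = 0.5`
  default matters at small n).
* The motivating analysis reports a headline share of variance
  "roughly 11%, computed as 100 × (0.238 − 0.191)/(1 − 0.191)"; that
  printed formula evaluates to ≈5.8%.  The package implements the
  formula as printed and makes no attempt to guess which number was
  intended.
* Variable-selection priors (spike-slab, BayesB/C), exon-level
  annotation and rsID lookup are out of scope.
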