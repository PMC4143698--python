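# wgrvar

Partitioning the phenotypic variance of systolic blood pressure across
subsets of sequence variants with Bayesian whole-genome regression.

## The problem

How much of the person-to-person variation in a complex trait do
different classes of genetic variant account for?  Rare variants are
invisible to association scans that rely on linkage disequilibrium with
common tags, yet may jointly carry much of the signal; variants inside
genes may matter more than those in the surrounding sequence.  This
package estimates, for a cohort with sequence genotypes and a
longitudinal blood-pressure phenotype, the proportion of variance of
standardized log systolic blood pressure (logSBP) explained by the
*simultaneous* regression on a whole set of markers — all of them, only
the genic ones, only the very rare ones, and so on — rather than by
single-marker tests.

It is aimed at statistical geneticists who want a self-contained,
reproducible implementation of the variance-partitioning workflow:
a synthetic-data generator with the relevant structure, phenotype
preparation, variant classification, the Gibbs sampler, and the
marker-number-controlled resampling comparison.

## The model

For individual *i*,

```
y_i = mu + sum_j Z_ij gamma_j + sum_l x_il beta_l + eps_i
```

where `y` is logSBP standardized to unit variance, `Z` holds the
nongenetic covariates (age, sex, smoking, blood-pressure medication)
with flat-prior fixed effects `gamma`, and `x_l` are marker dosages
expressed as deviations from twice the coded-allele frequency.  Marker
effects are iid `N(0, sigma_beta^2)` (Bayesian ridge / GBLUP-style
shrinkage), and `sigma_beta^2`, `sigma_eps^2` carry weakly informative
scaled-inverse-chi-square priors.  All full conditionals are conjugate
and the model is fitted by Gibbs sampling (default: 25,000 kept samples
after a 15,000-iteration burn-in).  Because `Var(y) = 1`, a model's
explained variance is simply

```
R^2_m = 1 - sigma_eps^2-hat(m)
```

with `sigma_eps^2-hat` the posterior mean of the residual variance.

Variants are classified by folded minor allele frequency — very rare
(MAF < 1%), rare (1% ≤ MAF ≤ 5%), common (MAF > 5%) — and by region —
genic (inside a gene's transcribed interval, introns included) versus
flanking (within ±50 kb outside one).  Crossing the axes with their
margins gives 12 marker sets; each is fitted jointly with the
covariates.  Because the sets differ hugely in size, each is also refit
on 500 markers drawn at random without replacement, 500 times, and
summarised as mean ± SD of the replicate `R^2` values.

## Worked example

```python
import wgrvar as w
from wgrvar.classify import annotate_variants

spec = w.SimSpec(n_subjects=395, n_variants=2000, seed=42)
sim = w.simulate_dataset(spec)

cohort, _ = w.prepare_cohort(sim["phenotypes"])
order = {f"S{i+1:05d}": i for i in range(spec.n_subjects)}
X = sim["X"][[order[s] for s in cohort["subject_id"]]]
y = cohort["y"].to_numpy()
Z, _ = w.build_covariate_matrix(cohort)

ann = annotate_variants(sim["variants"], X, sim["genes"])
sets = w.build_marker_sets(ann)
Xc, _ = w.center_genotypes(X)

mcmc = w.MCMCConfig(n_iter=4000, burn_in=1000)
r2_cov = w.gibbs_fit(y, Z, None, mcmc=mcmc).r_squared
r2_all = w.gibbs_fit(y, Z, Xc[:, sets["all_all"].indices], mcmc=mcmc).r_squared
print(f"covariates only : R^2 = {r2_cov:.3f}")
print(f"all markers     : R^2 = {r2_all:.3f}")
print(f"marker increment: {r2_all - r2_cov:.3f} "
      f"(simulated share {sim['truth']['realized']['marker_share']:.3f})")
```

prints

```
covariates only : R^2 = 0.204
all markers     : R^2 = 0.551
marker increment: 0.346 (simulated share 0.337)
```

The covariates-only model explains ~0.20 of the variance; adding the
2,000 markers raises `R^2` to 0.55, and the increment (0.346) recovers
the variance share the generator actually injected through marker
effects (0.337).  `BayesianWGR` is a scikit-learn estimator
(`fit(X, y, Z=...)`, `predict`, `get_params`), so it also composes with
sklearn tooling directly.

A command-line interface mirrors the library:

```bash
wgrvar simulate --seed 1 --out data/
wgrvar prep --pheno data/phenotypes.tsv --out data/
wgrvar classify --vcf data/genotypes.vcf --genes data/genes.bed --out data/
wgrvar fit --vcf data/genotypes.vcf --cohort data/cohort.tsv --seed 1 --out fit/
wgrvar run-all --config config.yaml          # the whole pipeline
```

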