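# Methods

## The model

`zinbda` estimates diet-associated fold changes of genome-resolved
metagenomic features from a caged-animal design. For feature (genome) *j* in
sample *i* the observed count is zero-inflated negative binomial:

```
y_ij = 0                                  with probability pi_j
y_ij ~ NB(eta_ij, phi_j)                  otherwise
log(eta_ij) = x_i beta_j + z_i u_j + log(depth_i)
```

* `x_i` — intercept plus dummy-coded diet (reference level omitted; the
  reference is configurable, default the alphabetically first level).
* `z_i` — one-hot cage indicator. Mice housed together exchange microbes
  (coprophagy), so samples within a cage are correlated; `u_j` is a
  per-feature, per-cage random effect absorbing that correlation.
* `depth_i` — the sample's total count, recomputed from the table. The log
  offset makes `beta` describe *relative*, not absolute, abundance.
* `phi_j` — NB dispersion in the mean/dispersion parameterization,
  `Var = mu + mu^2/phi`; Poisson as `phi -> inf`.
* `pi_j` — the probability that an observation of feature *j* is a
  structural ("non-biological") zero, applied independently per observation.
  The zero indicator is always marginalized analytically; no discrete latent
  variable is sampled.

Priors, as fitted: `pi_j ~ Beta(1.5, 1.5)`, `1/phi_j ~ half-Cauchy(0, 3)`,
every regression coefficient `~ Normal(0, sd 5)` (the intercept included),
every cage effect `~ Normal(0, sd 2)`. Normal scales are read as standard
deviations, the convention of the probabilistic languages these models are
written in. The half-Cauchy prior is placed on the inverse dispersion;
evaluated as a density in `phi` it carries the Jacobian `phi^-2`.

### Compositional coordinates

Sequencing yields compositions: only ratios are identified. Each feature is
fit independently (the likelihood factorizes over features), and raw
coefficients are converted per posterior draw to additive log-ratio (ALR)
coordinates by subtracting the reference feature's coefficient — by default
the first feature of the table. Any per-sample compositional constant
absorbed by the depth offset cancels in this subtraction; the reference's
own ALR coordinate is identically zero. Centred log-ratio (CLR) coordinates
subtract the across-feature mean of the ALR vector (the implicit zero
included), so CLR effects sum to zero across features within every covariate
and draw; reported summaries (posterior mean, sd, central credible interval
from empirical type-7 quantiles) are on the CLR scale. CLR coordinates of
raw coefficients are invariant to the choice of reference.

## Sampling

The sampler is an adaptive Metropolis-within-Gibbs on the unconstrained
scale (raw coefficients, `logit(pi)`, `log(1/phi)`), vectorized across
features: every block move proposes one scalar per feature simultaneously,
and the marginalized likelihood of the whole table is evaluated as one
matrix operation, with the `Gamma(y + phi)` terms cached between dispersion
updates. Step sizes adapt per parameter per feature during warmup
(Robbins-Monro toward 0.44 acceptance, the scalar-update optimum; rate
`t^-0.6`) and are frozen afterwards.

Because cages are nested within diets, each diet dummy is an exact linear
combination of its cages' indicators: the likelihood identifies only
`beta_d + u_c` and the posterior has an exact ridge resolved by the priors.
Scalar moves mix very slowly along that ridge, so the sampler adds
likelihood-invariant *translation* moves — add `delta` to a diet coefficient
and subtract it from the effects of exactly the cages housed under that
covariate (all cages, for the intercept) — accepted on the prior ratio
alone. Without these moves split R-hat on such designs is ~2; with them the
standard recovery run reaches R-hat near 1.05 at 2 chains x 1000 draws.

Initialization: coefficients from a ridge-regularized (lambda = 1) linear
fit of `log((y + 0.5) / depth)`; cage effects zero; `logit(pi)` from the
feature's zero fraction clipped to [0.02, 0.98]; `log(1/phi) = 0`. A
non-finite starting posterior is retried up to five times with Gaussian
jitter. Chains (default 4; at least 2, required by split diagnostics) use
seeds spawned deterministically from one master seed, so runs are exactly
reproducible. Convergence is summarized per scalar parameter with
rank-normalized split R-hat and bulk effective sample size (via ArviZ);
exceeding the thresholds (R-hat 1.05, ESS 100 by default) warns and flags
the run report but does not fail, mirroring common practice.

Options `fix_pi` / `fix_phi` pin those parameters (e.g. `fix_pi=0` turns
zero inflation off), and `depths=` overrides the offset; both exist mainly
for validation against deterministic quadrature, where the model must
collapse to a two-parameter posterior integrable on a grid.

## Synthetic data

The generator draws data with exactly the model's structure: lognormal
depths (default median 1e6 reads, log-sd 0.3, so the 1,273,062-read depth
filter used for real data is exercisable), per-feature baselines
`Normal(log(1/n_features), 1)` on log relative abundance (column totals then
track nominal depth), per-feature diet effects `Normal(0, beta_sd)`, cage
effects `Normal(0, u_sd)`, dropout `Beta(1.5, 1.5)` and dispersions
`LogNormal(log 5, 0.5)`. Cages are nested in diets (two cages of five mice
per diet by default, matching a four-diet, eight-cage design). Structural
zeros are realized per observation: a strictly per-feature indicator would
delete whole rows, which is not what dropout in sequencing data looks like
and would make the parameter unidentifiable.

Two generator defaults deserve comment:

* `u_sd = 0.5`, not the prior's 2. The fitting prior on cage effects is
  *weakly informative* — deliberately wider than realistic cage-to-cage
  variation. Because the diet coefficient is prior-identified against its
  cages (see above), its posterior-mean error has sd ~ `u_sd_true/sqrt(2)`
  under this design; cage noise at the prior's own scale (±7-fold between
  cages) would exceed any realistic diet effect.
* `beta_sd = 1.0` (~2.7-fold effects, a typical diet-responder scale). Much
  larger effect scales let a single feature take >90% of a small
  composition's reads, at which point the observed-depth offset tracks that
  feature's dropout rather than sequencing effort and the generator's own
  "log relative abundance" parameterization stops being meaningful.

What the generator does *not* emulate: taxonomic correlation structure,
phylogeny, read-level noise, true compositional closure (counts are
independent NB draws, so column sums only approximate the nominal depth),
batch effects, or covariation between abundance and genome annotation
quality. Passing recovery tests therefore demonstrates correctness of the
inference on data matching the model's assumptions, not performance on real
metagenomes.

The annotation generator produces genome -> reaction tables in which exactly
`floor(complete_fraction * n_genomes)` genomes carry all reactions of each
pathway and every other genome misses at least one. Optionally the first
pathway's complete set is *planted* as the genomes with the largest true
effect for a chosen diet covariate, giving a known positive
completeness-effect association for validating the correlation stage.

## Recovery and calibration scenario

The recovery and interval-calibration checks use a simulation-based
calibration design: 30 features, 4 diets x 2 cages x 5 samples, truths drawn
from the fitting priors (`beta_sd = 5`, `u_sd = 2`). With cages nested in
diets, interval width in the diet direction is set by the cage prior
regardless of data, so coverage is calibrated only when truth and prior
agree — with matched truth, 95% CLR intervals cover at ~96% and the
posterior-mean ALR effects correlate with truth at r ≈ 0.92-0.95 (2 chains x
1000 draws after 1000 warmup, ~10 s on one core). Dropout in this scenario
is `Beta(1.5, 8.5)` (mean 0.15) rather than the generator default: at mean
dropout 0.5 with ten samples per diet, roughly a quarter of feature-diet
contrasts retain at most one nonzero observation, and no inference method
recovers a contrast that was never observed. Dropout recovery itself is
checked separately (single feature, 200 samples, true `pi = 0.3`).

Sampler correctness is checked against deterministic 2-D grid quadrature
(step 0.01 on [-5, 5]^2) on a reduced model — one feature, two groups, fixed
dispersion, no zero inflation, no cages — where the posterior mean from MCMC
must agree within 0.05 (observed: < 0.01).

## Pathway completeness and validation

Completeness of pathway *p* in genome *g* is
`|reactions of p annotated in g| / |reactions of p|`, a proportion in
[0, 1]; a genome is *complete* only at exactly 1. Each pathway's
completeness column is Spearman-correlated (tie-corrected: Pearson on
midranks) against the CLR posterior means of a chosen diet covariate; CLR
rather than ALR means are used because they do not depend on the arbitrary
reference (ALR is available via `beta_to_alr`). Two-sided p-values come from
exhaustive permutation enumeration for n <= 9 (exact even under ties) and
the t approximation with n-2 degrees of freedom otherwise.

The model-free validation takes, per sample, the natural-log ratio of summed
counts of complete genomes over incomplete genomes. A pseudocount (default
1) is added to each *sum*, not each count; sequencing depth cancels in the
ratio, so raw and relative abundance give identical values. Ratios are
compared between diet groups by one-way ANOVA with Fisher's least
significant difference post hoc tests: pairwise t statistics using the
pooled ANOVA error variance on N-k degrees of freedom, unadjusted for
multiplicity (LSD's defining property; with two groups it reduces exactly to
the pooled-variance t-test). Diet is the only factor exposed here. Degenerate
partitions (no complete or no incomplete genome) are an explicit error, and
an all-equal response yields an undefined (NaN) F rather than an exception.

## Numerical notes and limitations

* All mixture densities are evaluated in log space with `logaddexp`;
  overflowing proposals produce `-inf` likelihoods and are rejected rather
  than propagating NaN.
* `pi` exactly 0 or 1 is handled through `log(0) = -inf` semantics; prior
  evaluation outside the support returns `-inf`, not an exception.
* Posterior draws serialize to a long-format TSV at 12 significant digits;
  summaries survive a round trip to that precision.
* No multiplicity adjustment is applied to CLR effects: they are reported as
  posterior means with credible intervals, not p-values.
* The sampler is a random-walk method: for tables with many thousands of
  features or very long chains a gradient-based sampler would be more
  efficient; the vectorization across features keeps the intended scale
  (tens to hundreds of genomes) fast.
* The depth used in the offset is recomputed after sample filtering; since
  filtering only removes whole samples, pre- and post-filter totals of a
  retained sample are identical.
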