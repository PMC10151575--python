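# Methods

`sowpop` implements a Bayesian analysis chain for a binary culling trait in
sows — culling for pelvic organ prolapse (POP) — observed across parities 2-6
on commercial farms. This note records the models, the conventions and the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Trait definitions and contemporary groups

Two codings of the same underlying outcome are used:

* **Across-parity**: one record per culled or dead sow, y = 1 if the removal
  reason was POP and y = 0 for any other removal reason. Only sows removed in
  parities 2-6 enter; removal parity is an additional fixed effect.
* **By-parity** (one dataset per parity 2-6): one record per sow at risk in
  that parity, y = 1 if she was removed in that parity for POP, y = 0 if she
  was not removed or was culled for another reason. A sow removed in a later
  parity (including >6) contributes controls to the parities she completed.

The fixed contemporary group is herd x year x quarter (HYQ) of the relevant
insemination date, with calendar quarters (Jan-Mar = Q1). Litter size is
carried in the record type but deliberately excluded from all default models:
a large fraction of culled sows have no litter-size record for the removal
parity, and conditioning on it could absorb genetic variation in
susceptibility.

Quality control removes whole sows on three individually switchable rules:
died without a recorded removal date; any insemination-to-farrowing interval
over 116 days; inconsistent pedigree (self-parenting, or a parent born after
the sow when birth dates are supplied). Sows with *missing* sire (pooled
semen) are retained and counted.

## Threshold (liability) models

All binary models are latent-liability models: l = Xb + u + e with y =
1{l > 0}, fitted by Gibbs sampling with truncated-normal data augmentation.
Fixed effects have flat priors and are updated level-wise; when two factors
are present (HYQ and removal parity) the second factor is re-anchored to a
zero reference level after each update, with the shift absorbed into the
first factor, so the confounded location cannot drift.

The latent residual variance is fixed by the link, because it is not
identifiable from binary data: 1 for probit, pi^2/3 ~ 3.2899 for the logit
scale. The "logit" animal model is implemented as probit augmentation with
the residual variance fixed at pi^2/3 — an approximation to true logistic
residuals (exact Polya-Gamma augmentation is deliberately out of scope) that
keeps heritability on the conventional logit scale, h2 = sigma2_a /
(sigma2_a + pi^2/3).

Truncated-normal draws invert the CDF on the *small* tail side, which stays
accurate for extreme linear predictors; a final clip (|l| >= 1e-10 on the
correct side) guards against underflow beyond ~37 residual sd.

### Marker-effects models (Bayes-B / Bayes-C / Bayes-Cpi / Bayes-C0)

Genotype doses (0/1/2) are centred by twice the allele frequency. Marker n
has effect beta_n included with probability 1 - pi (pi is the prior
probability of a *zero* effect):

* **Bayes-C**: included effects share a common variance sigma2_beta with a
  scaled-inverse-chi-square(nu=4, S) prior; S is set so the prior mean of the
  total genetic variance corresponds to a prior heritability of 0.3
  (user-adjustable; the data dominate quickly at the sample sizes used).
* **Bayes-Cpi**: pi gets a uniform prior and a beta-binomial Gibbs update.
* **Bayes-B**: marker-specific variances, each scaled-inverse-chi-square.
* **Bayes-C0**: pi = 0 (every marker in the model) — equivalent to GBLUP.

Inclusion indicators use the marginalized ratio with the effect integrated
out. Monomorphic markers are skipped with delta forced to 0. The intended
GWAS flow mirrors the source analysis: estimate pi with Bayes-Cpi, then run
Bayes-B at that pi.

**Genetic variance convention.** The genome-wide genetic variance saved with
each posterior sample is the *realized* variance across the analysed
individuals of the genetic values M beta (not 2*sum p q beta^2). The same
convention applies per 1 Mb window. Consequence worth knowing: with dense
non-sparse priors (Bayes-C0) at modest n, posterior sampling noise in beta
inflates the realized variance somewhat; sparse priors (Bayes-B/Cpi) are
nearly unbiased in the recovery simulations.

### Threshold animal model

For relationship-matrix models (pedigree A by the tabular method, or VanRaden
method-1 G with observed allele frequencies), the stabilized matrix
K* = 0.99 K + 0.01 I is eigendecomposed once; breeding values are sampled in
the eigenbasis, where their full conditional is an *independent* normal per
component (the likelihood precision is isotropic because each sow has one
record), giving an exact block update and fast mixing. sigma2_a has a
scaled-inverse-chi-square(nu=4) prior with scale from the 0.3 prior
heritability. Heritability samples use the sampled sigma2_a over
sigma2_a + sigma2_e(link); the realized variance of the breeding values is
stored alongside.

### Bivariate linear Bayes-C0

Between-parity genetic correlations come from a two-trait *linear* model on
the 0/1 phenotypes (the bivariate threshold model is poorly identified; on
correlations the linear model is a standard, adequate substitute). Marker
effect pairs are MVN(0, G2x2) with an inverse-Wishart(nu=4) update; residual
pairs MVN(0, R2x2), also inverse-Wishart. Sows observed in only one of the
two parities have the missing trait's residual drawn from its conditional
given R each iteration (data augmentation); a complete-case mode exists for
testing. Each saved sample stores the 2x2 covariance across individuals of
the genetic values M B; the genetic-correlation sample is the sampled
covariance over the product of sampled genetic standard deviations, and
samples with either variance below 1e-12 are dropped and counted.

## Posterior summaries

* **HPD intervals**: shortest contiguous window containing ceil(mass * n)
  sorted samples. This matches an exhaustive search over windows by
  construction and agrees with `coda`/`arviz`-style intervals up to one order
  statistic.
* **Observed-scale heritability** (Dempster-Lerner): h2_obs = h2_liab * z^2 /
  (p (1-p)) with p the trait incidence, t the upper-p normal quantile and z
  the normal density at t. The normal liability is used regardless of the
  link the latent model was fitted with — this is the standard conversion and
  reproduces the published 0.35 -> 0.12 and 0.21 -> 0.07 values at 10.1%
  incidence.
* Posterior standard deviations are reported where REML software reports
  standard errors; they are not the same quantity.

## Window-based GWAS summaries

Markers are assigned to non-overlapping 1 Mb windows, 0-based half-open
(window k covers [k Mb, k+1 Mb)), labelled by the integer Mb index. For each
saved sample the window's genetic-value variance across individuals is
divided by that sample's genome-wide genetic variance (ratio first, then
posterior mean — the alternative, ratio of posterior means, is not used and
the choice is documented here because the source tables do not state theirs).

* **WPPA** = fraction of samples in which the window's variance proportion
  exceeds rho; rho defaults to 1/(total genome windows spanned by the map,
  empty windows included) and is configurable — the recovery studies use
  rho = 0.01 with a ~100-window genome.
* **Significance**: windows explaining strictly more than 1% of the genetic
  variance.
* **Regional aggregation**: a by-parity signal for an across-parity anchor
  window is the sum of window shares within +/- 2 Mb on the same chromosome,
  truncated at chromosome ends; windows without markers contribute zero.

Under a *null* trait the genome-wide genetic variance is near zero and the
per-sample proportions become unstable ratios; WPPA then reflects how often a
window harbours any currently-included marker. With realistic genome
geometry (on the order of a hundred windows, ~10 markers per window) this
false-positive ceiling stays below 0.5; with very few windows it does not —
which is why the GWAS recovery scenario uses a 100 kb marker spacing.

## Synthetic data

The generator emulates the *structure* the analyses assume, with known ground
truth:

* **Genotypes**: haplotypes from a first-order Markov chain with stationary
  frequencies uniform on the MAF range (0.05-0.5) and adjacent-marker
  correlation ld_rho (default 0.3; chains restart at chromosome boundaries),
  summed into doses; ~1 marker / 25 kb in the default map.
* **Parity-specific architecture**: a sparse QTL set (default 2% of markers,
  matching pi ~ 0.98). QTL effects follow an AR(1) across parity whose
  innovation is Gram-Schmidt-orthogonalized in the genetic-value metric, so
  the realized adjacent-parity genetic correlation equals rg (default 0.7)
  *exactly* even with few QTL; longer lags decay approximately as rg^|k-l|.
  Effects are rescaled per parity so the realized liability-scale
  heritability equals the target exactly (defaults 0.41 down to 0.15 for
  parities 2-6).
* **Culling process**: liability l = g + HYQ + N(0,1) per parity; a sow
  develops POP in the first parity whose liability exceeds a threshold set as
  the empirical quantile of the liabilities of sows *actually at risk* —
  survivors are selected for low liability, so a marginal normal-theory
  quantile would under-realize the target incidence (defaults rising from
  0.35% to 3% of sows present). Other-reason culling strikes independently at
  9x the POP incidence, making POP ~10% of removals, as in the source
  population; an optional confounded mode correlates other-reason culling
  with liability. Removed sows generate no later records; parity-1 records
  are generated but excluded by the trait coders.
* **Pedigree and records**: sows are assigned sires/dams from founder pools
  (~n/40 sires, ~n/8 dams); 2% of sows have their sire blanked (pooled
  semen). Dates are constructed so clean data pass QC untouched (gestation
  113-116 d; ~40% of removed sows culled before farrowing).

Not emulated: seasonal or secular incidence trends, genotyping error or
missingness (mean imputation exists but the generator emits complete data),
selection of parents on the trait, and any pooled-semen paternity mixture
beyond blanking the sire. Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the model's own assumptions,
not robustness to real-data artefacts.

Two focused generators serve the recovery studies: a single-trait probit
liability scenario (default balanced incidence, which maximizes information
per record; the trait incidence of the recovery studies is not pinned down by
the source design) and a GWAS scenario planting ~2% of the genetic variance
on one mid-window QTL with moderate local LD (ld_rho = 0.5 at 100 kb
spacing) over a ~100-window genome. A 2%-of-genetic-variance window at
n = 3,000 binary records is a genuinely borderline signal (~0.8% of
phenotypic variance): across simulation replicates its WPPA at rho = 0.01
typically lands between 0.6 and 1.0, exceeding 0.8 in roughly two-thirds of
realizations, and the estimated share scatters about +/- 1 percentage point
around the truth. Recovery tests therefore use seeded replicates with a
majority (4-of-5) rule rather than asserting every realization.

## Chain settings and problem sizes

`ChainConfig` presets mirror the source analyses: 50,000 iterations / 5,000
burn-in / thin 100 for GWAS runs and 120,000 / 20,000 / 100 for bivariate
runs. The recovery studies and tests run reduced chains (typically 2,500 /
500 / 5 at n = 1,000-3,000 sows and p = 400-1,000 markers), chosen as the
smallest sizes at which the exact block updates mix well and posterior means
stabilize; all runs are exactly reproducible from their seeds, and numba
compiles the marker-update kernels once per session.

## Known limitations

* The logit animal model approximates logistic residuals by a rescaled
  probit; heritabilities agree closely but individual liabilities are not
  logistic draws.
* Realized-variance summaries inflate the genetic variance of dense-prior
  (Bayes-C0) fits at small n, as noted above; the GBLUP-equivalence check is
  therefore run at n = 2,000 where the effect is within the stated 0.05 band.
* Window variance shares over unlinked markers sum to ~100%; under LD the
  shares are not additive and no such identity holds.
* No convergence diagnostics are enforced (fixed-length chains); `arviz` can
  be pointed at the saved TSV samples if diagnostics are wanted.
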