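# Methods

## Model and scope

The package maps quantitative trait loci (QTL) for the *parameters of a
temporal trend* rather than for single-time-point measurements. The data
model has three layers.

**Within-individual trend.** Each individual's repeated measurements are a
straight line in centred time, `y_ik = mu_i0 + mu_i1 t_ik + e_ik`, with
i.i.d. Gaussian residuals. Centred integer time codes (nine consecutive
years map to −4..4, even counts to half-integers) make the intercept the
individual's mean across rings, which is the biologically meaningful
"stable level" trait; the slope is the annual rate of change. Nonlinear
(exponential/logistic) trend shapes are deliberately out of scope: over a
~9-ring window of young trees the linear term dominates and anything more
flexible mostly fits inter-annual weather noise.

**Between-individual genetics.** Intercepts and slopes receive multi-marker
regressions on binary (0/1) marker codes. Substituted into the trend this
yields the random-intercept/random-slope mixed model

    y_ik = a0 + a1 t_ik + alpha_i0 + alpha_i1 t_ik
           + sum_j x_ij beta_j + sum_j x_ij t_ik gamma_j + eps_ik,

with `(alpha_i0, alpha_i1) ~ MVN(0, Sigma)` and
`eps ~ N(0, sigma0^2)`. Its marginal moments,
`Var(y_ik) = sigma0^2 + S11 + 2 t S12 + t^2 S22` and
`Cov(y_ik, y_ih) = S11 + (t_k + t_h) S12 + t_k t_h S22`, are exposed as
`blmm.marginal_moments` and double as simulation oracles in the tests.

**Markers.** The intended design is a full-sib pseudo-testcross: dominant
presence/absence markers heterozygous in one parent segregate 1:1 and are
analysed as a backcross. The simulator produces exactly this (plus linkage
via Haldane's map function); 1:2:1-segregating co-dominant markers are not
simulated.

## Two estimation routes

### Multilevel LASSO (two-step)

Step 1 is per-individual ordinary least squares. Individuals observed
fewer than 4 times (out of the 9-ring design) are excluded — more than
five missing measurements leaves too little support for a slope.
`resid_var_hat` uses denominator `n_obs − 2` and is flagged undefined at
`n_obs = 2`. Traits with only 2–3 assessments (grain angle, microfibril
angle, stiffness) skip the trend fit; each assessment is analysed
separately.

Step 2 penalises the latent-trait regressions with an L1 penalty. The
solver is an exact LARS-lasso homotopy (entry *and* drop events),
implemented in-package because two of the decision rules are defined
directly on the path: the covariance test needs the knot sequence and
refits restricted to a previous active set at an interior penalty, and
stability selection reads a fixed-size active set off each subsample's
path. The objective convention is `1/2 ||y − Xb||^2 + lambda ||b||_1`;
KKT at every knot (`|x_j' r| <= lambda`, equality on the active set) is a
tested invariant, and dense-grid coordinate descent (scikit-learn's
`Lasso`) is the independent oracle. Predictors are standardised
internally and effects reported on the original 0/1 coding; the intercept
is never penalised; missing genotype codes are mean-imputed. The penalty
is chosen at the minimum of the 10-fold cross-validation curve (no 1-SE
rule), with folds assigned by seeded permutation into contiguous blocks;
intercept and slope analyses use independent seeded folds.

### Post-selection decision rules

* **Single-p** — each selected marker re-estimated alone by OLS with a
  t-test, multiplied by the *total* marker count (a p-marker Bonferroni
  screen). Simple and slightly anti-conservative because the selection
  step is ignored; it is the baseline the other rules improve on.
* **MST-p** — repeated random half-splits: lasso-CV selection on one
  half, multiple-regression t-tests (Bonferroni by selected-set size) on
  the other, unselected markers at p = 1; per-marker p-values combined by
  quantile aggregation
  `min(1, (1 − log g_min) inf_{g in [g_min,1]} min(1, Q_g({p_b / g})))`
  with `g_min = 0.05`. Markedly conservative, by construction.
* **COV-p** — at the k-th entry knot,
  `T_k = (<y, X b(l_{k+1})> − <y, X_A b~_A(l_{k+1})>) / sigma^2` with
  `A` the active set before entry and `b~_A` the lasso refit restricted
  to `A`; `p = exp(−T_k)` under the asymptotic Exp(1) null. The variance
  estimate is the full-model OLS residual variance when `n > p + 1`,
  otherwise the CV-lasso residual variance. The Exp(1) null is asymptotic
  in the panel size: at p = 100 the finite-p error is still visible to a
  2000-replicate KS test, so the calibration suite uses p = 300
  orthonormal predictors, where it is not.
* **SSP** — 1000 seeded half-subsamples (without replacement), each
  contributing the path active set whose size is closest to
  `q_target = 10`; the SSP is the selection frequency. Fixing the
  per-subsample size makes `q` in the threshold bound exact:
  `pi = (1 + q^2 / (E(V) p)) / 2` bounds the expected number of false
  selections by `E(V)`. With q = 10 this gives 0.83 / 0.66 for a
  153-marker panel (E(V) < 1 / < 2) and 0.66 / 0.58 for a 319-marker
  panel — `q = 10` is the only integer q jointly reproducing all four.

A marker is *suggestive* when any of Single-p, MST-p, COV-p or its
marker-level BFDR (its LFDR, the prefix of size one) is below 0.2, or its
SSP reaches the E(V) < 2 threshold; *significant* when at least two of the
three p-statistics are ≤ 0.05, or the SSP reaches the E(V) < 1 threshold,
or the marker is BFDR-selected at alpha = 0.05.

### Bayesian linear mixed model (one-step)

Priors: flat on `(a0, a1)`; Jeffreys on `sigma0^2`;
`Sigma ~ Inv-Wishart(I_2, 1)` (an improper/boundary prior — the posterior
degrees of freedom `1 + n` are proper for n ≥ 2, which is guarded);
per effect the spike-and-slab mixture with `r_j ~ Bernoulli(0.5)` and
slab variance `sigma_j^2 ~ Inv-Gamma(0.1, 0.1)`. Intercept and slope
effects of the same marker carry independent indicators and independent
slab variances. When `r_j = 0` the slab variance is refreshed from its
prior, keeping the chain on the full parameter space.

The sampler is a **partially collapsed Gibbs scheme**, derived as follows.
Marker effects and random intercepts both act at the individual level, so
an indicator update conditioned on the current random effects barely sees
the marker: worse, a null marker that happens to absorb part of the
between-individual variance becomes self-sustaining (the random effects
adapt around it) and its indicator can stay at 1 essentially forever. We
observed exactly this failure in a conditional implementation (a pure-null
marker pinned at PIP 1.0). The production sampler therefore integrates
out, analytically, both the candidate effect *and* the random effects when
sampling each indicator: under the marginal likelihood the per-individual
covariance is `V_i = sigma0^2 I + W_i Sigma W_i'` with `W_i` the
per-individual `[1, t]` design, and all inner products reduce to 2×2
Woodbury identities over per-individual aggregates, so a full sweep costs
O(n p). The scan order is: (i) per marker, `r_j` from its Bernoulli
conditional with the effect integrated out, then the effect from its
Gaussian conditional if included; slab variances; (ii) fixed effects by
the analogous collapsed GLS draw; (iii) random effects imputed from their
exact bivariate Gaussian conditional; (iv) `Sigma` from
`Inv-Wishart(Psi + sum_i a_i a_i', upsilon + n)`; (v) `sigma0^2` from its
scaled inverse-chi-square conditional. Because nothing between the
collapsed updates and the re-imputation of the random effects conditions
on the random effects, the kernel leaves the joint posterior invariant.
Equivalence with an independent naive sampler (numerical-quadrature
indicator updates conditioned on the random effects) is verified on a
small fixture to PIP agreement within 0.03.

Defaults are 20,000 iterations with 10,000 burn-in and no thinning,
configurable; the examples and tests use shorter chains (1,200–12,000
iterations), which the seeded-reproducibility and two-chain-agreement
tests show to be sufficient at those problem sizes. Traits with 2–3
assessments use the reduced model: scalar random intercepts
(`tau^2 ~ Inv-Gamma(upsilon/2, Psi_11/2)`, the scalar analogue of the
Wishart block) and no slope effects; more than 3 time points raises an
error directing callers to the full model.

Selection: PIP = posterior mean of `r_j`; LFDR = 1 − PIP; the BFDR rule
sorts LFDRs ascending and selects the largest prefix whose mean is below
alpha, reporting that mean as the set-level BFDR. Reported posterior-mean
effects are unconditional (shrunken by the PIP); conditional effects are
the ratio effect/PIP.

## Reporting

`H²_QTL` is the latent-trait variance explained by called (suggestive +
significant) QTL jointly: `Var_i(sum_j x_ij effect_j) / Var_i(latent)` for
the two-step route; for the one-step route the denominator is the
random-effect variance plus the genetic-score variance. Values can exceed
1 only when effects and variances come from different fits; this is
flagged, not clipped.

Genotype trajectories for a slope QTL on a proportion trait: the
population mean (percent) is moved to the arcsine-square-root degree scale
`T(p) = arcsin(sqrt(p))` *in degrees* — the degree convention is canonical
here because a 0.23 deg/yr effect then reproduces both published endpoint
predictions (42.2% / 40.3%) to one decimal, which radians do not. The
population percent-per-year trend is linearised onto that scale by the
delta method, `dT/dp = 1/(2 sqrt(p(1−p)))` at the mean (endpoint
differencing drifts by ~0.1 points over five years). With 0/1 coding and
1:1 segregation the two genotype classes sit at ± half the effect around
the population slope, so their average recovers the population curve
exactly (a tested identity). Back-transformed predictions outside [0,
100]% are clipped with a warning. Effect-size ratios divide |effect| by
the population mean (intercept QTL) or by the transformed-scale population
mean slope (slope QTL of proportion traits; using the mean slope — not the
mean level — is what matches the ~13% figure for the earlywood trend
marker, and that reading is adopted).

## Synthetic data

`synthetic.simulate_pedigree_genotypes` draws the first marker of each
linkage group Bernoulli(1/2) and propagates along the group with flip
probability `r = (1 − exp(−2d/100))/2` (Haldane, no interference — the
standard default absent crossover-interference information). Layout tuples
`(count, spacing)` place markers on a fixed grid at that spacing, so the
"average spacing" is realised exactly; explicit position arrays are
accepted for full control (zero distances give duplicated columns,
arbitrarily large ones give independence). Genotype codes are complete by
default: marker/individual filtering for genotyping quality belongs
upstream of analysis, and downstream code mean-imputes whatever sparse
missingness it is given.

`simulate_longitudinal_traits` draws exactly from the mixed model above
and removes observations independently at `missing_rate` (missing
completely at random per individual × time cell; the field data motivating
the design were >95% complete). The returned truth record carries the
realised random effects for recovery tests. The earlywood-percentage
default parameter set works on the transformed degree scale: mean 48.615
deg (back-transforms to 56.3%), trend −1.733 deg/yr (−3.0 %/yr by the
delta method), nine centred annual codes, intercept/slope SDs 2.54 deg and
0.81 deg/yr mapped from the phenotypic SDs 4.4% and 1.4%/yr, zero
intercept–slope correlation (none is reported for the motivating data),
residual SD 2 deg (a plausible ring-to-ring fluctuation on that scale; the
source tables do not identify the within-tree residual separately), 5%
missingness. These defaults are fixed study conditions, not tuning knobs.

`simulate_radial_density_profile` builds, per ring, a monotone
piecewise-linear density waveform from `wd_min` to `wd_max` whose first
`earlywood_fraction` of width spans the lowest 20% of the density range
and last `latewood_fraction` the top 20%, so the span-threshold
designation recovers the requested fractions by construction; both at 0.2
degenerate to an exact linear ramp. Positions are midpoints of a uniform
grid (20 points/mm by default), which makes ramp quantiles exact.

What the generator does *not* emulate: co-dominant 1:2:1 markers, linkage
disequilibrium beyond within-group recombination, genotype-by-environment
interaction beyond the marker × time terms, non-Gaussian residuals,
informative missingness, and the proprietary ring-boundary detection of
real density profiles (boundaries are required inputs — the motivating
pipeline identified them with instrument-specific software plus manual
checks). Passing tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to these real-data features.

## Numerical choices and edge cases

* Ring designation applies the earlywood test before the latewood test;
  with a tiny density span both `<=`/`>=` conditions can hold at once and
  earlywood wins. Constant-density rings raise a degenerate-ring error.
* Component proportions are width proportions (each sampled point weighted
  by the interval it represents, partitioning the ring at midpoints); for
  uniform sampling this equals point counting. Empty components are
  reported absent, not zero.
* Homotopy tie-breaks: joining events at equal penalty prefer the lowest
  marker index; of a duplicated column pair at most one is ever active.
  Constant columns are excluded with a warning. An event cap (20p + 100)
  guards against numerically cycling knots.
* CV ties prefer the larger penalty (sparser model). Residual variance at
  the selected penalty uses `RSS/(n − k − 1)` with `k` selected markers,
  falling back to `RSS/n` when degrees of freedom run out.
* Non-positive-definite inverse-Wishart draws (numerically possible at
  boundary scales) are retried with jittered scale and counted in the
  chain diagnostics.
* The Bernoulli-indicator logit is clipped at ±700 before
  exponentiation.

## Test problem sizes

Monte-Carlo suites run at sizes chosen for a serial laptop-class run:
covariance-test calibration 2000 replicates at n = 600, p = 300;
multi-split familywise error 200 replicates at n = 80, p = 15 with 20
splits; Bayesian recovery on one n = 300, p = 100 dataset (three planted
QTL, 1500-iteration chain); moment checks at n = 10,000 individuals.
Power/null examples use 20–60 seeds each. These sizes are the package's
own trade-off between resolution and runtime.

## Known limitations

* Single-chain MCMC by default; convergence is assessed in tests by
  cross-seed PIP agreement, not by formal diagnostics (no R-hat).
* Single-p inherits post-selection bias; it is reported as the baseline
  it is, never as calibrated inference.
* The covariance test's Exp(1) null is asymptotic; p-values on small
  panels (tens of markers) are approximate.
* H² for the one-step route uses the posterior-mean plug-in rather than a
  full posterior of explained variance.
* Min-CV lasso overselects under weak signal; that is precisely why the
  four decision rules, not the selected set itself, drive QTL calls.
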