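# Methods

## The model

`allomap` maps quantitative trait loci (QTLs) that act on the *allometric
scaling* between two longitudinal leaf traits rather than on any single
trait value. The traits are petiole length P (cm), leaf length L (cm) and
leaf area A (cm²), measured weekly on a recombinant inbred line (RIL)
population grown under two planting densities — a high density that
triggers the shade-avoidance syndrome and a low-density control. The two
relations of interest are L→A (leaf *shape*) and P→L (leaf *position*).

### Mean structure

Within one progeny i, density d ∈ {h, l} and SNP genotype j ∈ {0, 1}
(RILs are fully homozygous, so each biallelic SNP has two classes), the
response trajectory follows the power law evaluated at the progeny's own
predictor trajectory:

    mu_ijd(t) = alpha_jd * x_id(t) ** beta_jd

The predictor x enters as data, not as a parameter: allometry is a
relation between traits, and using each progeny's measured x keeps the
between-progeny variation in growth vigor out of the QTL contrast.
The joint observation vector stacks the high-density weeks (T_h = 7 by
default) and the low-density weeks (T_l = 8).

### Covariance structure

Residuals follow a first-order structured antedependence model (SAD(1))
per density: each week's residual is a phi-weighted carry-over of the
previous week's residual plus an independent innovation with variance
sigma². Stacked over both densities,

    Sigma = Lambda Sigma_eps Lambda'

with Lambda unit lower triangular holding powers of phi (phi_h over the
high-density chain, phi_l over the low-density chain) and
Sigma_eps = sigma² I. Three consequences we rely on:

* Sigma is positive definite for *every* real phi — no constraint is
  needed during optimization.
* det Sigma = sigma^(2(T_h+T_l)): the log-determinant does not involve phi.
* The formulation with a diagonal V = diag(phi_h, phi_l) and diagonal
  Sigma_eps forces the cross-density covariance block to zero. We surface
  this rather than hide it: the two density blocks are independent by
  construction. An opt-in innovation cross-correlation `rho` (default 0)
  couples innovations at weeks shared by the two grids, for users who want
  a nonzero cross block; the scan never fits it.

sigma² is shared across densities (the parameter set is phi_h, phi_l,
sigma²) and across progenies. Per-progeny missing weeks are handled by
row/column deletion of Sigma, which for a SAD chain is exactly the
marginal distribution (Markov property).

### Likelihood, hypotheses, statistics

The likelihood is the product over progenies of multivariate-normal
densities with genotype-specific mean curves. Three nested hypotheses are
fitted by maximum likelihood:

* **H1** — genotype-specific (alpha_jd, beta_jd): 8 mean + 3 covariance
  parameters.
* **H0 (pooled)** — genotype classes share one curve per density: the
  QTL-existence null. LR = −2(logL0 − logL1), LOD = LR / (2 ln 10).
* **H0 (density-equal)** — each genotype shares its curve across
  densities (alpha_jh = alpha_jl, beta_jh = beta_jl) while the covariance
  keeps density-specific phis: the genotype-by-environment interaction
  null, tested only after a locus is significant in the main scan (a
  configurable choice). Note this null constrains *both* genotype
  classes, so when the population-baseline allometry itself differs
  between densities (as it does under shade avoidance, and in the
  generator's defaults) the statistic is large at essentially every
  locus; it measures density dependence of the fitted curves at the
  locus, not a pure genotype-by-density contrast.

Genome-wide significance comes from a permutation null: whole progenies
(their high- and low-density series together, preserving the joint
covariance) are reassigned against the genotype matrix; the threshold is
the (1 − level) empirical quantile ("higher" interpolation, i.e. an order
statistic) of per-permutation maximum LR values. The default level is
0.01 with 1000 permutations; 0.05 is exposed alongside. The pooled-null
likelihood is permutation-invariant, so it is fitted once per dataset.

### Numerical strategy

Because Lambda is unit triangular, its inverse is unit lower *bidiagonal*,
and the likelihood factors exactly through the innovation representation

    z_k = (r_k − phi^(t_k − t_prev) r_prev) / sqrt(v_k),
    v_k = sum over grid weeks t_m in (t_prev, t_k] of phi^(2(t_k − t_m)),

where t_prev is the progeny's previous *observed* week and v_k > 1 only
when intermediate weeks are missing. Each group's scale alpha enters the
whitened residual linearly and is profiled by generalized least squares in
closed form; sigma² is profiled as the whitened residual sum of squares
over the observation count. What remains is a derivative-free Nelder–Mead
search over the beta exponents and (phi_h, phi_l) only — 6 dimensions
under H1, 4 under either null — implemented in numba. Initialization is
the per-group log-log OLS slope with phi started at the lag-1
autoregression of the OLS residuals; by default 3 starts are run (the
OLS/lag-1 start, a phi = 0 start, and a jittered start). On simulated
scans a single start reaches the same optimum to ~1e-9, so the
runtime-sensitive Monte Carlo studies and the acceptance script use
`n_starts = 1`; the default stays at 3 for robustness on irregular data.
Convergence is declared at 1e-9 on the profiled objective (≈ 5e-10 on
logL) and 1e-6 on the simplex. A dense-covariance evaluation path
(`sad.log_density` + `scan.model_loglik`) implements the identical model
through explicit Cholesky factorization; the test suite holds the two
routes to within 1e-8.

Degenerate inputs: tiny negative LRs from finite tolerances are clamped
to 0; a genotype group smaller than 5 progenies (paper-silent choice)
skips the SNP with a flagged record; a profiled alpha is floored at 1e-12
when reported; R² with zero response variance is defined as 1 and
flagged degenerate.

## Effect summaries

The additive effect at predictor value x is
a_d(x) = (alpha_1d x^beta_1d − alpha_0d x^beta_0d)/2, antisymmetric under
label swap. PVE uses the two-homozygote variance-components convention:
with class frequencies p + q = 1, genetic variance 4pq·a_d(x̄(t))² at the
progeny-mean predictor x̄(t), divided by the observed phenotypic variance
of the response at that week, averaged over weeks and densities (a
per-week *maximum* variant is exposed via `mode="max"`; the source
analyses do not state which convention produced their PVE figures, so
both are provided and the averaged one is the default).

## The synthetic-data generator

No real dataset accompanies the motivating study, so `allomap.simulate`
generates data with exactly the structure the likelihood assumes:

* **Genotypes.** 84 progenies, 5 chromosomes, 400 SNPs/chromosome by
  default (a desk-scale stand-in for a ~4×10⁵ SNP panel), simulated
  directly at the terminal homozygous generation as a first-order Markov
  chain along each chromosome with inter-SNP recombination fraction 0.02
  — marginally equivalent to forward simulation of 10 selfing
  generations and far cheaper. Causal columns are drawn from a dedicated
  random substream and flanking markers are extended outward from the
  causal anchor, so phenotypes (and the causal genotypes) are invariant
  to the SNP count while local linkage is preserved.
* **Growth.** Petiole length follows a logistic curve per density with
  progeny-level lognormal multipliers on (K, r) shared across densities.
  The S-shape is a design choice (the source describes sigmoid growth
  without naming an equation) and is pluggable. Default constants were
  fixed once by root-finding so the three population mean curves cross
  between densities near weeks 3.2 (P), 3.7 (L) and 4.1 (A), with the
  high-density curve overtaking — the qualitative signature of shade
  avoidance.
* **Allometry chain.** L = alpha_PL,d · P^0.9 + SAD(1) noise, then
  A = alpha_LA,d · L^1.8 + SAD(1) noise, with slight density-specific
  baseline alphas (that is what staggers the three crossover weeks).
  Default innovation variances (0.010 for L, 0.040 for A, phi ≈ 0.8–0.85)
  leave progeny-level allometry R² ≈ 0.99, comfortably above the ≥ 0.9
  screening threshold. Default causal effects act multiplicatively on
  alpha (log-scale separation 0.028 for P-L, 0.059 for L-A), giving each
  locus a generating PVE near 1.5% — the order of magnitude reported for
  real shade-avoidance QTLs.
* **Floor.** Additive Gaussian residuals are unbounded below, so traits
  are clipped at 0.02 cm; at default noise the clip never triggers.

What the generator does *not* emulate: replicate-level (within-progeny)
variance — the likelihood operates on progeny means, and no within-progeny
dispersion figures are available to calibrate it; measurement error in
the predictor trait; linkage-map estimation; segregation distortion; and
any non-Gaussian residual behavior. Passing tests therefore demonstrate
correctness of the machinery under its own model assumptions, not
robustness to their violation on real data.

## Monte Carlo study sizes

Chosen once for binomial resolution on a single CPU and stated here as
the package's own design:

* **Recovery under noise**: 100 replicates at n = 200 progenies, 7/8-week
  design, innovation variance 0.1 (progeny R² ≈ 0.95). This study uses a
  milder growth design (week-1 trait values well above the positivity
  floor) so that additive noise at that level never truncates — clipping
  would bias the recovery assessment.
* **Type-I error calibration**: 200 independent null datasets × 8
  unlinked SNPs × 39 permutations at level 0.05 (with n_perm = 39 the
  order-statistic threshold has exact exchangeability level 2/40 = 0.05);
  the family-wise rejection fraction is required to sit in [0.02, 0.09].
* **Power**: 50 seeds, n = 200, a causal locus whose alpha separation
  (0.0512) puts its generating PVE near 5%; detection required in ≥ 95%
  of seeds.

## Known limitations

* The scan fits two genotype classes only; residual heterozygous calls
  are recoded to missing, not modeled as a third class.
* Permutation thresholds currently require complete genotype matrices.
* The H1 optimizer profiles alpha without a positivity constraint; on
  adversarial data the profiled alpha could be non-positive (it is
  floored only in reporting).
* LR null distributions for the interaction test are referenced against
  chi-square quantiles only informally (4 constrained parameters); the
  package makes no asymptotic claim, and users needing exact interaction
  thresholds should permute.
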