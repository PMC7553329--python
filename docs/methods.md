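# Methods

This note documents the models, estimators, numerical choices and known
limitations of `prsum`. Notation: `N` training-GWAS sample size, `n`
reference-panel size, `p` SNP count, `b_j`/`var(b_j)` the marginal GWAS
effect and its variance, `s_j^2` the SNP dosage variance estimated from the
panel, `R` an LD (correlation) matrix, `beta` PRS weights.

## Penalized regression on summary statistics

### Objective and lambda convention

All fitting is done on the standardized (correlation) scale. Per LD block,

    f(beta) = (1-s) beta' R beta + s beta' beta - 2 beta' r + J(beta)

with `r_j` the SNP-phenotype correlation and `J` the penalty. The quadratic
is deliberately *unhalved*, and the L1 part of every penalty carries a
factor 2 (`J_lasso = 2 lambda ||beta||_1`, elastic net
`2 alpha lambda ||beta||_1 + (1-alpha) lambda ||beta||^2`, TLP
`2 lambda sum min(|beta_j|, tau)`). Under this pairing the coordinate
update at `s = 1` is literally `beta_j = S(r_j, lambda)` — the tuning
parameter **is** the soft-threshold magnitude, so grids are interpretable on
the correlation scale (`lambda = 0.05` kills marginal correlations below
0.05 at identity LD). Other packages may halve the quadratic; their lambdas
are half of ours.

### Computing r from published per-allele effects

Published effects are per-allele, not correlations. The default conversion
uses the exact identity for simple linear regression,
`r_j = t_j / sqrt(n_j - 2 + t_j^2)` with `t_j = b_j / se_j`, which requires
no phenotype-SD estimate. An alternative `r_j = b_j s_j / sd(y)` is
selectable (`r_method="beta_sd"`); it needs a phenotype SD, for which the
moment-based estimate below is used by default. Both are clipped to
[-1, 1].

### Solvers

LASSO and elastic net: cyclic coordinate descent with an incrementally
maintained `R beta` (numba kernel). Convergence: max absolute coordinate
change < `tol` (default 1e-6), cap 10 000 sweeps per block; non-convergence
is reported as a flag on the model, never silently and never as an
exception. The objective is non-increasing across sweeps (exact coordinate
minimization of a convex function).

TLP is nonconvex. Two regimes:

* **Blocks of <= 8 SNPs: exact.** `min(|b|, tau) = min_{w in {0,1}} [w |b| +
  (1-w) tau]`, so the global minimum is the best of the `2^d` convex
  weighted-LASSO problems. Each is solved by coordinate descent; the best
  objective wins. Verified against an independent zoomed-grid brute-force
  oracle to < 1e-14 on random fixtures.
* **Larger blocks: difference-of-convex (DC).** Weights
  `w_j = 1{|beta_j| <= tau}` (ties penalized) define an inner weighted
  LASSO with thresholds `lambda w_j`; iterate until the weight set is
  stable (outer cap 50). The DC loop is run from two starts — the LASSO
  solution at the same `(lambda, s)` and the unpenalized solution — and the
  better local minimum is kept. Single-start DC from the LASSO solution
  alone demonstrably sticks in poor local minima when the truth has effects
  above `tau`; the unpenalized start covers that regime. The TLP objective
  is non-increasing across outer iterations (majorize-minimize).

Warm starts: within each `(kind, s, tau, alpha)` grid slice, lambdas are
solved in descending order, each solution initializing the next.

SNPs absent from the reference panel are treated as mutually independent
(their LD sub-matrix is zero; the `s` and `1-s` diagonal terms sum to one)
and solved exactly from the univariate objective
`beta^2 - 2 beta r + J(beta)` — soft threshold for LASSO, shrunken soft
threshold for the elastic net, and an explicit two-branch comparison for
TLP.

### Harmonization

Intersection by SNP id; swapped allele coding flips the effect sign;
palindromic (A/T, C/G) SNPs are always removed — no strand inference is
attempted. Panel MAF filter (default 0.01). Greedy LD clumping within
blocks guarantees no retained pair with r² above the cutoff (default 0.9,
needed for coordinate-descent convergence); priority is ascending training
p-value, ties broken by position (absent target data there is nothing
better to prioritize on). Panel missing genotypes are mean-imputed per SNP
before any variance/LD computation, which keeps `R` a valid correlation
matrix. Coordinates: bim positions are 1-based, block BED intervals 0-based
half-open; a SNP maps to a block iff `start <= pos - 1 < end`, and SNPs
outside every interval become singleton pseudo-blocks. Harmonization is
idempotent.

### Rescaling

Standardized weights are converted to per-allele weights by
`beta_j * sd(y) / s_j`; `sd(y)` defaults to the moment estimate
`sqrt(med_j [n_j se_j^2 s_j^2 + s_j^2 b_j^2])`. Scores computed from
per-allele weights on raw dosages equal scores from standardized weights on
panel-standardized dosages up to an affine transform, so correlations and
r² are unaffected by the choice.

## Pseudo-AIC / pseudo-BIC

Sample-size-normalized moment estimates: `(1/N) X'X` by the panel-half
covariance per block, `(1/N) X'Y` by `s_j^2 b_j`, and `(1/N) Y'Y` by the
median (configurable: mean) across SNPs of `N s_j^2 var(b_j) + s_j^2 b_j^2`.
From these, `SSE-hat = N (yty - 2 c'xty + c' Cov c)` with `c` the model
weights on the centered-dosage scale, `sigma2 = N/(N-q) (yty - xty_S'
Cov_S^{-1} xty_S)` over a SNP subset `S` of size `q`, log-likelihood
`l = -SSE/(2 sigma2)`, and `AIC = 2k - 2l`, `BIC = ln(N) k - 2l`. Ties in
either criterion break toward smaller `k`.

Numerical choices and their rationale:

* **Covariance regularization.** The selection-side covariance is
  regularized by a constant 0.2 *on the correlation scale*:
  `Cov + 0.2 diag(s^2) = D^{1/2} (R + 0.2 I) D^{1/2}`. The constant is
  meaningful relative to a unit diagonal; applying `+0.2 I` literally on the
  dosage-variance scale (diagonal entries `2f(1-f) <= 0.5`) would over-shrink
  low-MAF SNPs and inflate `sigma2` by 25–40% against an individual-level
  OLS oracle in simulation, versus ~10% with the proportional form. The
  regularization itself biases `sigma2` upward by design — it trades a
  small optimistic-fit bias for positive-definiteness.
* **sigma2 subset.** Pruning and thresholding: greedy clump at r² < 0.2,
  keep p < 1e-3, cap at `min(500, N/4)` SNPs; `q` = subset size. The
  thresholds are defaults, not doctrine — the estimate is fairly flat over
  reasonable choices, and all are configurable. An empty subset degrades
  gracefully to `sigma2 = yty` (the null-trait value).
* **Degrees of freedom.** Either the nonzero-weight count, or the ridge
  trace `tr[(R_sub + lambda*s I)^{-1} R_sub]` computed blockwise on the
  correlation sub-matrix of SNPs with nonzero weights. Restricting to the
  active set is essential — otherwise the trace is the same for every
  candidate. The shrinkage scalar is taken as the fitting-grid
  `lambda * s` applied against the unit-diagonal correlation blocks; this
  is a convention (the trace argument's normalization is ambiguous between
  per-n and raw cross-product scalings) and is flagged as such. A singular
  block at `lambda*s = 0` falls back to the nonzero count with a warning.
* **Panel splitting.** Using the same panel for fitting and selection
  biases the criteria optimistically. `split_reference_panel` produces
  disjoint seeded halves with provenance tags, and `estimate_moments` /
  `pseudo_criteria` raise on detected reuse.

**Exactness check.** When the training genotypes themselves serve as the
panel, the regularization is zero, and the summary statistics use the
moment convention (`se^2 = RSS/(N s^2 N)`, no intercept on centered data),
all three moment identities are algebraically exact, so `SSE-hat` and
`sigma2` reproduce the individual-level values to machine precision. The
test suite asserts this recovery limit; it is the ground truth anchoring
the approximations.

## Quasi-correlation

`quasiCor = sum_j s_j^2 b*_j c_j / sqrt(var(Y*) c' Cov_r c)` with `c` the
PRS weights on the centered-dosage scale, `b*` the testing-cohort marginal
effects (allele-harmonized; sign-flipped where coding is swapped), `Cov_r`
the **unregularized** per-n panel covariance (the derivation has no
regularizer, unlike the selection-side covariance), and `var(Y*)` the
median moment identity applied to the testing summary statistics. Weights
given as standardized betas are divided by `s_j`; the global phenotype-SD
factor cancels in a correlation. Finite-panel noise can push the ratio
outside [-1, 1]; it is clipped with a warning rather than an error. In the
no-split limit (testing data as its own panel, moment-matched statistics)
the quasi-correlation equals the Pearson correlation between the PRS and
the testing phenotype exactly.

## Binary traits

Matching the first two Taylor terms of the linear and logistic mean
functions gives `beta0 = 1/(1+e^{-b0})`, `beta1 = kappa b1`,
`se(beta1) = kappa se(b1)` with `kappa = e^{-b0}/(1+e^{-b0})^2 in (0, 1/4]`
and `e^{-b0}` = control:case ratio. When both an intercept and counts are
available, counts win (covariate-adjusted intercepts do not reflect the
marginal case fraction). The approximation degrades with large `b1`; at
GWAS effect sizes the converted effects correlate > 0.999 with direct
linear-probability regression in simulation. Converted tables carry a
`converted_from_logistic` flag and are treated as quantitative downstream.
Covariate-adjusted conversion is out of scope.

## The simulator

What it emulates: genome-like block LD (per block, two latent AR(1)
standard-normal haplotypes per individual thresholded at the per-SNP MAF
quantile and summed — HWE holds by construction and adjacent-SNP dosage
correlation is a deterministic, Monte-Carlo-verifiable function of the
latent rho); point-normal architectures with an exact causal count
`m = round(p M)` drawn without replacement and effects `N(0, h2/m)` (the
exact count stabilizes sparse-regime comparisons against the true model
size; at `m = pM` the per-SNP variance matches the usual `h2/(Mp)`);
clustered architectures for allelic heterogeneity (anchor SNPs with at
least one in-block neighbor at r² >= 0.25 are extended to groups of 2–8
causal SNPs — an emulation of the qualitative regime, not a reproduction of
any specific published procedure); additive phenotypes with noise
calibrated on the training cohort's empirical genetic variance so the
realized variance ratio targets `h2`; liability-threshold binary traits at
a configured case fraction. The default cohort sizes follow the canonical
6240/3119/1560/1560 four-way split (training statistics / fitting panel /
selection panel / evaluation).

What it does not emulate: recombination-map realism, population structure
and relatedness, MAF-dependent effect architectures, genotyping error, and
cross-block LD. Passing tests therefore demonstrate correctness of the
estimators under block-independent LD with well-behaved allele frequencies,
not robustness to confounding or model misspecification in real cohorts.

The marginal GWAS scan is vectorized OLS (classic n-2 SE and t test by
default; the `ml` convention `var(b) = RSS/(N s^2 N)` reproduces the moment
identities exactly and exists for the recovery limits) and a vectorized
per-SNP Newton logistic fit for binary traits (agrees with a reference
implementation to 1e-6). Monomorphic SNPs are excluded.

## Problem sizes used in validation

The validation experiments run at reduced-but-faithful scale chosen once:
heritability calibration at the canonical N = 6240 with M = 2000;
quasi-correlation fidelity at M = 2000, N_train = 4000, n_test = 3000 over
20 seeds; sparsity orderings at `p_causal = 0.001`, `s = 0` over 20 seeds;
allelic heterogeneity at M = 1000 with latent rho 0.8 over 20 seeds. These
sizes keep each experiment in the minutes range on one core while leaving
the qualitative contrasts (TLP sparser and more accurate under clustering,
BIC sparser than AIC, quasiCor² tracking r² to ~0.01–0.03) far from their
decision boundaries.

## Known limitations

* Degrees-of-freedom normalization for the ridge trace is a documented
  convention, not a derived result.
* `sigma2` inherits an upward bias of order 10% from the deliberate
  covariance regularization; criteria comparisons are unaffected because
  `sigma2` is shared across candidates.
* The quasi-correlation denominator assumes the panel covariance
  approximates the testing-cohort covariance; ancestry-mismatched panels
  will bias it.
* No summary-statistic imputation, no liftover, no multi-ancestry panels,
  no cross-block LD, and no inference (p-values/intervals) on penalized
  estimates.
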