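# prsum

Polygenic risk scores from GWAS summary statistics: penalized regression with
a reference LD panel, model selection without validation data (pseudo-AIC /
pseudo-BIC), and out-of-sample accuracy from summary statistics alone
(quasi-correlation).

## The problem

A polygenic risk score (PRS) is a weighted sum of allele dosages predicting
the genetic component of a trait. Modern GWAS rarely share individual-level
genotypes; what is public is, per SNP, the marginal effect estimate, its
standard error, the sample size and a p-value, plus external reference panels
from which linkage disequilibrium (LD) can be estimated. `prsum` builds,
selects and evaluates sparse PRS models in exactly that regime — no
individual-level data at any stage.

## The model

With standardized phenotype and genotypes, the SNP-phenotype correlations
`r = X_s' y_s` come from the summary statistics and the LD matrix
`R = X_r' X_r` from a reference panel. The weights minimize, per LD block,

```
f(beta) = beta' R_s beta - 2 beta' r + J(beta),     R_s = (1 - s) R + s I
```

where the `s`-regularization keeps the two-dataset problem well posed, and
`J` is one of

* **LASSO** `J = 2 lambda ||beta||_1` — sparse, uniformly biased toward zero;
* **elastic net** `J = 2 alpha lambda ||beta||_1 + (1-alpha) lambda ||beta||^2`;
* **TLP** (truncated LASSO penalty) `J = 2 lambda sum_j min(|beta_j|, tau)` —
  stops penalizing effects above `tau`, reducing bias and increasing
  sparsity when the truth is sparse or causal SNPs cluster within LD regions
  (allelic heterogeneity).

Minimization is blockwise cyclic coordinate descent; the TLP runs a
difference-of-convex loop around a weighted-LASSO inner solve (exact
enumeration on small blocks). SNPs missing from the panel are treated as
independent and solved in closed form.

For a set of candidate models, the Gaussian log-likelihood is approximated
from summary statistics via the moment identities

```
(1/N) X'X ~ (1/n) Xr'Xr,   (1/N) Y'Y ~ med_j [N s_j^2 var(b_j) + s_j^2 b_j^2],
(1/N) X'Y ~ (s_1^2 b_1, ..., s_p^2 b_p)'
```

giving `SSE-hat`, a residual variance `sigma2-tilde` from a
pruned-and-thresholded OLS subset, and the criteria `AIC = 2k - 2l`,
`BIC = ln(N) k - 2l` with `l = -SSE/(2 sigma2)`. The reference panel must be
split: one half for fitting, the disjoint half for selection (enforced by a
provenance guard). Out-of-sample fit against a cohort known only through its
summary statistics `b*` is estimated by the quasi-correlation

```
quasiCor = sum_j s_j^2 b*_j beta_j / sqrt( var(Y*) * beta' Cov_r beta )
```

whose square approximates the predictive r². Binary-trait (logistic) summary
statistics are first converted to the linear scale via
`beta = kappa * b, kappa = e^{-b0}/(1+e^{-b0})^2`, with `e^{-b0}` the
control:case ratio.

A block-LD simulator (thresholded AR(1) latent haplotypes, point-normal or
clustered causal effects, liability-threshold binary traits) generates full
four-cohort studies so the whole stack is testable without any downloads.

## Worked example

`examples/04_quasi_correlation.py` simulates a study (1500 SNPs, h² = 0.5,
1% causal), fits a LASSO path from the training summary statistics with the
tune1 cohort as LD panel, tunes λ, and then scores the model against the
*summary statistics* of an unseen test cohort:

```
quasi-correlation            = 0.676
squared quasi-correlation    = 0.457
true test r2 (oracle check)  = 0.458
```

The squared quasi-correlation (0.457) recovers the true predictive r²
(0.458) that would require individual-level test data to compute directly.
The other examples cover simulation, fitting LASSO/TLP paths, pseudo-AIC/BIC
selection, and binary-trait conversion; each prints its numbers with a line
of interpretation. A thin CLI (`prsum simulate|fit|select|qcor|convert-binary|demo`)
wraps the same functions for shell use.

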