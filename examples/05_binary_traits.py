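"""Use case-control GWAS results with the linear-scale machinery.

Marginal logistic log-odds are converted to linear-probability effects via
the slope factor kappa = e^{-b0}/(1+e^{-b0})^2, where e^{-b0} is the
control:case ratio. For a balanced study kappa = 1/4. The converted table is
then valid input for pseudo-AIC/BIC and quasi-correlation.
"""

import numpy as np

from prsum import SimConfig, compute_gwas, convert_sumstats, simulate_study

cfg = SimConfig(n_snps=300, splits={"train": 6000}, h2=0.3, p_causal=0.1,
                binary=True, case_fraction=0.5, seed=5)
study = simulate_study(cfg)
X, y = study.genotypes["train"], study.phenotypes["train"].astype(float)

logistic = compute_gwas(X, y, snps=study.snps, binary=True)
converted = convert_sumstats(logistic, n_cases=int(y.sum()),
                             n_controls=int(len(y) - y.sum()))
direct = compute_gwas(X, y, snps=study.snps, binary=False)

corr = np.corrcoef(converted.df["beta"], direct.df["beta"])[0, 1]
print(f"cases / controls: {int(y.sum())} / {int(len(y) - y.sum())}")
print(f"kappa (balanced design): {0.25:.2f}")
print(f"correlation of converted vs direct linear-probability betas: {corr:.4f}")
print("(the Taylor-matching conversion is near-exact for the small per-SNP "
      "effects typical of GWAS)")
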