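"""Measure out-of-sample PRS accuracy when the test cohort shares only
summary statistics.

The quasi-correlation estimates the Pearson correlation between the PRS and
the testing phenotype from the testing cohort's marginal effects plus a
reference panel — no individual-level testing data. Its square approximates
the usual predictive r^2.
"""

import numpy as np

from prsum import (SimConfig, compute_gwas, fit_path, quasi_correlation_report,
                   simulate_study)
from prsum.pipeline import (default_lambdas, evaluate_r2, make_grid,
                            problem_from_study, tune_by_r2)

cfg = SimConfig(n_snps=1500, splits={"train": 3500, "tune1": 1500, "tune2": 1200,
                                     "test": 2000},
                h2=0.5, p_causal=0.01, seed=3)
study = simulate_study(cfg)
problem, panel = problem_from_study(study)
models = fit_path(problem, panel, make_grid("lasso", default_lambdas(8, 0.005, 0.08)))
best, _ = tune_by_r2(models, problem, study.genotypes["tune1"],
                     study.phenotypes["tune1"])
model = models[best]

# summary statistics are all we are allowed to see from the test cohort
test_ss = compute_gwas(study.genotypes["test"], study.phenotypes["test"],
                       snps=study.snps)
rep = quasi_correlation_report(model, problem, test_ss, study.panel("tune2"))

true_r2 = evaluate_r2(model, problem, study.genotypes["test"],
                      study.phenotypes["test"])
print(f"quasi-correlation            = {rep['quasi_correlation']:.3f}")
print(f"squared quasi-correlation    = {rep['quasi_correlation']**2:.3f}")
print(f"true test r2 (oracle check)  = {true_r2:.3f}")
print("(the squared quasi-correlation estimates the predictive r2 the model "
      "would achieve on the hidden individual-level test data)")
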