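"""Select a PRS model without any validation data via pseudo-AIC / pseudo-BIC.

The Gaussian log-likelihood of each candidate is approximated from summary
statistics and a second, disjoint reference panel (reusing the fitting panel
would optimistically bias the criteria — the provenance guard enforces the
split). BIC's ln(N) k penalty selects sparser models than AIC's 2k.
"""

from prsum import (SimConfig, estimate_moments, fit_path, pseudo_criteria,
                   simulate_study)
from prsum.pipeline import default_lambdas, evaluate_r2, make_grid, problem_from_study

cfg = SimConfig(n_snps=1000, splits={"train": 3000, "tune1": 1200, "tune2": 1200,
                                     "test": 800},
                h2=0.5, p_causal=0.005, seed=11)
study = simulate_study(cfg)
problem, fit_panel = problem_from_study(study)
models = fit_path(problem, fit_panel,
                  make_grid("lasso", default_lambdas(8, 0.01, 0.15), s_values=(0.0,)))

selection_panel = study.panel("tune2")       # disjoint from the fitting panel
moments = estimate_moments(problem, selection_panel)
report = pseudo_criteria(models, moments, panel_half=selection_panel, problem=problem)

print(report.table[["k", "sse", "pseudo_aic", "pseudo_bic"]].round(1))
print(f"residual variance estimate sigma2 = {report.sigma2:.3f} "
      f"(from a pruned-and-thresholded subset of {report.q} SNPs)")
for name, idx in [("pseudo-AIC", report.selected_aic), ("pseudo-BIC", report.selected_bic)]:
    m = models[idx]
    r2 = evaluate_r2(m, problem, study.genotypes["test"], study.phenotypes["test"])
    print(f"{name} selects model {idx}: {m.n_nonzero} nonzero weights, "
          f"test r2 = {r2:.3f}")
print(f"(true model has {len(study.causal)} nonzero effects; BIC is the "
      "sparser criterion)")
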