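"""End-to-end workflows tying the simulator, fitting and selection together.

These helpers implement the canonical four-cohort design: summary statistics
from a training cohort, one reference panel for fitting, a second disjoint
panel for model selection, and an evaluation cohort. They are what the demo
CLI, the examples and the validation experiments run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .fit import PenaltySpec, PRSModel, fit_path
from .io import HarmonizedProblem, ReferencePanel
from .qcor import select_by_quasicor
from .selection import estimate_moments, pseudo_criteria
from .simulate import SimConfig, SimStudy, compute_gwas, simulate_study

logger = logging.getLogger(__name__)

__all__ = [
    "default_lambdas",
    "make_grid",
    "problem_from_study",
    "evaluate_r2",
    "tune_by_r2",
    "run_demo",
]


def default_lambdas(n: int = 20, lo: float = 0.001, hi: float = 0.1) -> np.ndarray:
    """Logarithmically spaced soft-threshold grid."""
    return np.geomspace(lo, hi, n)


def make_grid(
    kind: str,
    lambdas,
    s_values=(0.1,),
    taus=(np.inf,),
    alphas=(1.0,),
) -> list[PenaltySpec]:
    """Cartesian tuning grid for one penalty family."""
    out = []
    for s in s_values:
        for lam in lambdas:
            if kind == "tlp":
                out.extend(PenaltySpec("tlp", float(lam), float(s), tau=float(t)) for t in taus)
            elif kind == "elastic_net":
                out.extend(
                    PenaltySpec("elastic_net", float(lam), float(s), alpha=float(a))
                    for a in alphas
                )
            else:
                out.append(PenaltySpec("lasso", float(lam), float(s)))
    return out


def problem_from_study(
    study: SimStudy,
    fit_panel_split: str = "tune1",
    se_method: str = "ols",
    **harmonize_kwargs,
) -> tuple[HarmonizedProblem, ReferencePanel]:
    """Training summary statistics harmonized against a fitting panel."""
    from .io import harmonize

    ss = compute_gwas(
        study.genotypes["train"],
        study.phenotypes["train"],
        snps=study.snps,
        binary=study.cfg.binary,
        se_method=se_method,
    )
    panel = study.panel(fit_panel_split)
    problem = harmonize(ss, panel, study.blocks, **harmonize_kwargs)
    return problem, panel


def evaluate_r2(
    model: PRSModel, problem: HarmonizedProblem, genotypes: np.ndarray, phenotype: np.ndarray
) -> float:
    """Squared Pearson correlation between the PRS and an observed phenotype.

    Weights are applied on the centered-dosage scale (standardized betas
    divided by the panel SD; the global factor does not affect r^2). SNPs
    absent from the panel are skipped.
    """
    d = problem.df
    rows = np.flatnonzero(problem.in_reference)
    cols = d["panel_col"].to_numpy()[rows]
    w = model.beta[rows] / d["s_hat"].to_numpy()[rows]
    score = genotypes[:, cols].astype(float) @ w
    if score.std() == 0 or np.std(phenotype) == 0:
        return 0.0
    return float(np.corrcoef(score, phenotype)[0, 1] ** 2)


def tune_by_r2(
    models: list[PRSModel],
    problem: HarmonizedProblem,
    genotypes: np.ndarray,
    phenotype: np.ndarray,
) -> tuple[int, np.ndarray]:
    """Index of the model maximizing r^2 on a tuning cohort."""
    scores = np.array([evaluate_r2(m, problem, genotypes, phenotype) for m in models])
    return int(np.argmax(scores)), scores


def run_demo(
    out_dir: str | Path,
    seed: int = 0,
    n_snps: int = 1000,
    p_causal: float = 0.01,
    h2: float = 0.5,
    scale: float = 0.5,
    dry_run: bool = False,
) -> dict:
    """Simulate a study, fit LASSO and TLP grids, compare selection criteria.

    Writes a per-criterion comparison table (selected model, nonzero count,
    test r^2) and a manifest with the configuration and seed. ``scale``
    shrinks the cohort sizes relative to the canonical 6240/3119/1560/1560
    split. Returns the manifest dictionary.
    """
    splits = {k: max(200, int(v * scale)) for k, v in
              {"train": 6240, "tune1": 3119, "tune2": 1560, "test": 1560}.items()}
    cfg = SimConfig(n_snps=n_snps, splits=splits, p_causal=p_causal, h2=h2, seed=seed)
    plan = {
        "version": _version,
        "seed": seed,
        "config": {
            "n_snps": n_snps, "p_causal": p_causal, "h2": h2, "splits": splits,
        },
        "stages": ["simulate", "fit", "select", "evaluate"],
    }
    if dry_run:
        print(json.dumps(plan, indent=2))
        return plan

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg)
    problem, panel_fit = problem_from_study(study)

    lambdas = default_lambdas(10, 0.002, 0.05)
    grid = make_grid("lasso", lambdas, s_values=(0.1,)) + make_grid(
        "tlp", lambdas, s_values=(0.1,), taus=(0.005, 0.02)
    )
    models = fit_path(problem, panel_fit, grid)

    panel_sel = study.panel("tune2")
    moments = estimate_moments(problem, panel_sel)
    report = pseudo_criteria(models, moments, panel_half=panel_sel, problem=problem)
    test_ss = compute_gwas(
        study.genotypes["tune2"], study.phenotypes["tune2"], snps=study.snps
    )
    qc_idx, qc_table = select_by_quasicor(models, problem, test_ss, panel_sel)
    tune_idx, _ = tune_by_r2(
        models, problem, study.genotypes["tune2"], study.phenotypes["tune2"]
    )

    rows = []
    for name, idx in [
        ("pseudo_aic", report.selected_aic),
        ("pseudo_bic", report.selected_bic),
        ("quasi_correlation", qc_idx),
        ("tuning_r2", tune_idx),
    ]:
        r2 = evaluate_r2(
            models[idx], problem, study.genotypes["test"], study.phenotypes["test"]
        )
        rows.append(
            {
                "criterion": name,
                "selected_model": idx,
                "penalty": models[idx].penalty.kind,
                "lambda": models[idx].penalty.lam,
                "n_nonzero": models[idx].n_nonzero,
                "test_r2": r2,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "selection_comparison.tsv", sep="\t", index=False)
    report.table.to_csv(out_dir / "pseudo_criteria.tsv", sep="\t", index=False)
    manifest = dict(plan, n_models=len(models), true_nonzero=int(len(study.causal)))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("demo artifacts written to %s", out_dir)
    return manifest
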