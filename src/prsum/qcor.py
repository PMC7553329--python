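"""Quasi-correlation: out-of-sample PRS fit from summary statistics alone.

For a PRS with weights ``b`` (applied to centered allele dosages) and a
testing cohort known only through its marginal effects ``beta*``, the
correlation between the score ``X* b`` and the testing phenotype ``Y*`` is
estimated as

    quasiCor = sum_j s_j^2 beta*_j b_j
               / sqrt( var(Y*) * b' Cov_r b )

where ``s_j^2`` and ``Cov_r = (1/n) Xr' Xr`` come from a reference panel
(covariance unregularized — the derivation has none) and ``var(Y*)`` is the
median of the per-SNP moment identities applied to the testing summary
statistics. The numerator is the empirical (1/n) Y*'X* b; the denominator
replaces the two variances by panel and summary estimates. Finite-panel
noise can push the ratio outside [-1, 1]; it is clipped with a warning.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .fit import PRSModel
from .io import HarmonizedProblem, InputError, ReferencePanel, SummaryStats
from .selection import SummaryMoments, estimate_moments

logger = logging.getLogger(__name__)

__all__ = ["quasi_correlation", "quasi_correlation_report", "select_by_quasicor"]


def quasi_correlation(
    weights: np.ndarray,
    beta_star: np.ndarray,
    s2: np.ndarray,
    cov_blocks: list[tuple[np.ndarray, np.ndarray]],
    var_y_star: float,
) -> float:
    """Quasi-correlation from pre-aligned arrays.

    ``weights`` are PRS weights on the centered-dosage scale, ``beta_star``
    the testing-cohort marginal effects for the same SNPs, ``s2`` panel SNP
    variances, ``cov_blocks`` (positions, covariance) pairs covering the
    SNPs, ``var_y_star`` the testing phenotype variance estimate.
    """
    w = np.asarray(weights, dtype=float)
    if not np.any(w != 0):
        raise InputError("quasi-correlation undefined for an all-zero model")
    if var_y_star <= 0:
        raise InputError("nonpositive testing-phenotype variance estimate")
    num = float(np.sum(s2 * beta_star * w))
    quad = 0.0
    for pos, C in cov_blocks:
        quad += float(w[pos] @ C @ w[pos])
    if quad <= 0:
        raise InputError("zero predicted-score variance in quasi-correlation")
    value = num / np.sqrt(var_y_star * quad)
    if abs(value) > 1.0:
        warnings.warn(
            f"quasi-correlation {value:.4f} outside [-1, 1]; clipped "
            "(finite-panel noise)",
            stacklevel=2,
        )
        value = float(np.clip(value, -1.0, 1.0))
    return float(value)


def _align_test_stats(
    problem: HarmonizedProblem, test_ss: SummaryStats, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Testing-cohort (beta*, var(beta*), n) aligned to problem rows.

    Alleles are matched against the harmonized orientation; swapped coding
    flips the sign of beta*. SNPs absent from the testing data get beta* = 0
    (they contribute nothing to the covariance identity).
    """
    t = test_ss.df.set_index("snp_id")
    d = problem.df
    beta = np.zeros(len(rows))
    var_b = np.full(len(rows), np.nan)
    n = np.full(len(rows), np.nan)
    for k, row in enumerate(rows):
        sid = d["snp_id"].iloc[row]
        if sid not in t.index:
            continue
        rec = t.loc[sid]
        a1, a2 = d["a1"].iloc[row], d["a2"].iloc[row]
        if (rec["a1"], rec["a2"]) == (a1, a2):
            sign = 1.0
        elif (rec["a1"], rec["a2"]) == (a2, a1):
            sign = -1.0
        else:
            continue
        beta[k] = sign * rec["beta"]
        var_b[k] = rec["se"] ** 2
        n[k] = rec["n"]
    return beta, var_b, n


def quasi_correlation_report(
    model: PRSModel,
    problem: HarmonizedProblem,
    test_ss: SummaryStats,
    panel: ReferencePanel,
) -> dict:
    """Quasi-correlation of one model against testing summary statistics.

    The model's standardized betas are converted to the centered-dosage
    scale (``beta_j / s_j``, the global phenotype-SD factor cancels in a
    correlation); ``panel`` supplies SNP variances and the blockwise
    unregularized covariance. Returns the estimate plus its components.
    """
    if test_ss.is_binary_trait:
        raise InputError("convert binary testing summary statistics first")
    moments = estimate_moments(problem, panel, reg=0.0)
    rows = moments.rows
    beta_star, var_b, n = _align_test_stats(problem, test_ss, rows)
    ok = np.isfinite(var_b)
    if not ok.any():
        raise InputError("no testing-cohort SNPs align with the problem")
    var_y = float(np.median(n[ok] * moments.s2[ok] * var_b[ok] + moments.s2[ok] * beta_star[ok] ** 2))
    w = model.beta[rows] / np.sqrt(moments.s2)
    value = quasi_correlation(w, beta_star, moments.s2, moments.cov_blocks_raw, var_y)
    return {
        "quasi_correlation": value,
        "var_y_star": var_y,
        "n_snps_aligned": int(ok.sum()),
        "n_nonzero": model.n_nonzero,
    }


def select_by_quasicor(
    models: list[PRSModel],
    problem: HarmonizedProblem,
    test_ss: SummaryStats,
    panel: ReferencePanel,
) -> tuple[int, pd.DataFrame]:
    """Pick the candidate with the largest quasi-correlation.

    Degenerate candidates (all-zero weights) receive NaN; ties break toward
    the sparser model. Raises if every candidate is degenerate.
    """
    if not models:
        raise InputError("no candidate models")
    if test_ss.is_binary_trait:
        raise InputError("convert binary testing summary statistics first")
    moments = estimate_moments(problem, panel, reg=0.0)
    rows = moments.rows
    beta_star, var_b, n = _align_test_stats(problem, test_ss, rows)
    ok = np.isfinite(var_b)
    if not ok.any():
        raise InputError("no testing-cohort SNPs align with the problem")
    var_y = float(
        np.median(n[ok] * moments.s2[ok] * var_b[ok] + moments.s2[ok] * beta_star[ok] ** 2)
    )
    values = []
    for m in models:
        try:
            w = m.beta[rows] / np.sqrt(moments.s2)
            values.append(
                quasi_correlation(w, beta_star, moments.s2, moments.cov_blocks_raw, var_y)
            )
        except InputError:
            values.append(np.nan)
    table = pd.DataFrame(
        {"quasi_correlation": values, "n_nonzero": [m.n_nonzero for m in models]}
    )
    if table["quasi_correlation"].isna().all():
        raise InputError("all candidate models are degenerate")
    order = sorted(
        range(len(models)),
        key=lambda i: (
            -(table["quasi_correlation"][i] if np.isfinite(table["quasi_correlation"][i]) else -np.inf),
            table["n_nonzero"][i],
        ),
    )
    return order[0], table
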