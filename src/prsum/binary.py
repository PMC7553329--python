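"""Conversion of logistic-regression GWAS results to the linear scale.

The selection and quasi-correlation machinery assumes linear-regression
summary statistics. For a binary trait analyzed by marginal logistic
regression with estimates ``(b0, b1)``, matching the first two Taylor terms
of the linear and logistic mean functions gives

    beta0 = 1 / (1 + e^{-b0})
    beta1 = kappa * b1,      se(beta1) = kappa * se(b1)

with ``kappa = e^{-b0} / (1 + e^{-b0})^2`` and ``e^{-b0}`` equal to the
control:case ratio of the study. ``kappa`` lies in (0, 1/4], maximal for a
balanced design. The approximation is accurate when ``b1`` is small — the
usual regime for individual SNP effects.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import InputError, SummaryStats

logger = logging.getLogger(__name__)

__all__ = ["logistic_to_linear", "convert_sumstats", "kappa_from_ratio"]


def kappa_from_ratio(control_case_ratio: float) -> float:
    """Slope factor e^{-b0} / (1 + e^{-b0})^2 from the control:case ratio."""
    if control_case_ratio <= 0:
        raise InputError("control:case ratio must be positive")
    e = control_case_ratio
    return e / (1.0 + e) ** 2


def logistic_to_linear(
    b1: np.ndarray | float,
    se_b1: np.ndarray | float,
    n_cases: int | None = None,
    n_controls: int | None = None,
    b0: float | None = None,
) -> tuple[float, np.ndarray | float, np.ndarray | float]:
    """Convert log-odds effects to linear-probability effects.

    ``e^{-b0}`` is taken from ``n_controls / n_cases`` when counts are given
    (counts win over an explicit intercept — robust to covariate-adjusted
    intercepts); otherwise from ``b0``. Returns ``(beta0, beta1, se_beta1)``.
    """
    if n_cases is not None or n_controls is not None:
        if not n_cases or not n_controls or n_cases <= 0 or n_controls <= 0:
            raise InputError("both n_cases and n_controls must be positive")
        if b0 is not None:
            logger.info("both intercept and case/control counts given; counts win")
        ratio = n_controls / n_cases
    elif b0 is not None:
        ratio = float(np.exp(-b0))
    else:
        raise InputError("need n_cases/n_controls or the logistic intercept b0")
    kappa = kappa_from_ratio(ratio)
    beta0 = 1.0 / (1.0 + ratio)
    return beta0, kappa * np.asarray(b1, dtype=float), kappa * np.asarray(se_b1, dtype=float)


def convert_sumstats(
    ss: SummaryStats, n_cases: int | None = None, n_controls: int | None = None,
    b0: float | None = None,
) -> SummaryStats:
    """Convert a binary-trait summary-statistics table to the linear scale.

    The output is flagged quantitative (``is_binary_trait=False``) so the
    downstream moment identities use the linear-scale SE; a
    ``converted_from_logistic`` column records the provenance.
    """
    if not ss.is_binary_trait:
        raise InputError("summary statistics are not flagged as a binary trait")
    d = ss.df.copy()
    _, beta, se = logistic_to_linear(
        d["beta"].to_numpy(), d["se"].to_numpy(),
        n_cases=n_cases, n_controls=n_controls, b0=b0,
    )
    d["beta"] = beta
    d["se"] = se
    d["converted_from_logistic"] = True
    return SummaryStats(d, is_binary_trait=False, n_dropped=ss.n_dropped)
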