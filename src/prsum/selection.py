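"""Pseudo-AIC / pseudo-BIC model selection from summary statistics.

Without individual-level data, the Gaussian log-likelihood of a candidate PRS
is approximated by replacing the moments of the training data with

    (1/N) X'X  ~  (1/n) Xr'Xr            (reference-panel covariance, blockwise)
    (1/N) Y'Y  ~  median_j( N s_j^2 var(beta_j) + s_j^2 beta_j^2 )
    (1/N) X'Y  ~  ( s_1^2 beta_1, ..., s_p^2 beta_p )'

where ``beta_j, var(beta_j)`` are the marginal GWAS results, and ``s_j^2``
the SNP dosage variances from the panel. The covariance is regularized as
``(1/n) Xr'Xr + c I`` (default c = 0.2) for numerical stability. From these,

    SSE-hat      = N ( yty - 2 b' xty + b' Cov b )          (b = centered-scale weights)
    sigma2-tilde = N / (N - q) ( yty - xty_S' Cov_S^{-1} xty_S )

with ``S`` a pruned-and-thresholded SNP subset of size ``q`` standing in for
the OLS fit, and the criteria are ``AIC = 2k - 2l``, ``BIC = ln(N) k - 2l``
with ``l = -SSE / (2 sigma2)``. The degrees of freedom ``k`` use either the
ridge trace ``tr[(R + lam*s I)^{-1} R]`` over the nonzero SNPs of each block
or simply the nonzero count.

The reference panel used here must be independent of the one used for
fitting — reusing it induces an optimistic bias — hence the provenance guard
and :func:`split_reference_panel`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import PRSModel
from .io import (
    HarmonizedProblem,
    InputError,
    ConfigurationError,
    ProvenanceError,
    ReferencePanel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryMoments",
    "SelectionReport",
    "estimate_moments",
    "estimate_sigma2",
    "estimate_sse",
    "degrees_of_freedom",
    "pseudo_criteria",
    "select_sigma2_subset",
    "split_reference_panel",
]


@dataclass
class SummaryMoments:
    """Sample-size-normalized moment estimates for the selection criteria.

    All vectors/matrices are restricted to the problem's in-reference SNPs,
    in problem row order; ``rows`` maps back to problem rows. ``cov_blocks``
    holds ``(positions-into-rows, regularized covariance)`` per LD block;
    ``cov_blocks_raw`` the unregularized versions.
    """

    yty_per_n: float
    xty_per_n: np.ndarray
    cov_blocks: list[tuple[np.ndarray, np.ndarray]]
    cov_blocks_raw: list[tuple[np.ndarray, np.ndarray]]
    s2: np.ndarray
    rows: np.ndarray
    N: float
    reg: float
    panel_provenance: str = ""

    @property
    def sd_y(self) -> float:
        return float(np.sqrt(self.yty_per_n))


def split_reference_panel(
    panel: ReferencePanel, seed: int
) -> tuple[ReferencePanel, ReferencePanel]:
    """Split a panel into disjoint halves (fit half, selection half).

    The halves carry provenance tags so that reuse of the fitting half on
    the selection side is detectable.
    """
    if panel.n_ref < 4:
        raise InputError("need at least 4 individuals to split a panel")
    rng = np.random.default_rng(seed)
    order = rng.permutation(panel.n_ref)
    half = panel.n_ref // 2
    fit = panel.take_individuals(order[:half], f"{panel.provenance}|seed{seed}|half-fit")
    sel = panel.take_individuals(order[half:], f"{panel.provenance}|seed{seed}|half-select")
    return fit, sel


def estimate_moments(
    problem: HarmonizedProblem,
    panel_half: ReferencePanel,
    reg: float = 0.2,
    center: str = "median",
    fit_panel_provenance: str | None = None,
) -> SummaryMoments:
    """Moment estimates from harmonized summary statistics and a panel half.

    ``panel_half`` must cover the problem's SNPs by id and must not be the
    panel used for fitting (checked against ``fit_panel_provenance`` when
    given). ``center``: "median" (recommended) or "mean" aggregation of the
    per-SNP (1/N) Y'Y identities.
    """
    if problem.is_binary_trait:
        raise InputError(
            "binary-trait summary statistics must be converted to the linear "
            "scale first (see prsum.binary.convert_sumstats)"
        )
    if fit_panel_provenance is not None and panel_half.provenance == fit_panel_provenance:
        raise ProvenanceError(
            "the reference-panel half used for fitting cannot be reused for "
            "model selection; split the panel and use the other half"
        )
    d = problem.df
    rows = np.flatnonzero(problem.in_reference)
    if rows.size == 0:
        raise InputError("no SNPs shared with the reference panel")

    lookup = {sid: j for j, sid in enumerate(panel_half.snps["snp_id"])}
    try:
        cols = np.array([lookup[sid] for sid in d["snp_id"].iloc[rows]])
    except KeyError as exc:
        raise InputError(f"panel half lacks SNP {exc.args[0]!r}") from None
    X = panel_half.imputed()[:, cols]
    Xc = X - X.mean(axis=0)
    s2 = (Xc**2).mean(axis=0)
    if np.any(s2 <= 0):
        raise InputError("zero-variance SNP in selection panel half")

    beta = d["beta"].to_numpy()[rows]
    var_b = d["se"].to_numpy()[rows] ** 2
    n_snp = d["n"].to_numpy()[rows]
    terms = n_snp * s2 * var_b + s2 * beta**2
    agg = np.median if center == "median" else np.mean
    if center not in ("median", "mean"):
        raise ConfigurationError(f"unknown center {center!r}")
    yty = float(agg(terms))
    xty = s2 * beta

    n_ref = panel_half.n_ref
    pos_of_row = {r: i for i, r in enumerate(rows)}
    cov_blocks, cov_raw = [], []
    for _, blk_rows in problem.block_groups():
        pos = np.array([pos_of_row[r] for r in blk_rows])
        C = Xc[:, pos].T @ Xc[:, pos] / n_ref
        cov_raw.append((pos, C))
        # reg is calibrated against a unit-diagonal (correlation) matrix, so on
        # the covariance scale it multiplies the SNP variances:
        # C + reg * diag(s^2) = D^(1/2) (R + reg I) D^(1/2)
        cov_blocks.append((pos, C + reg * np.diag(s2[pos])))
    return SummaryMoments(
        yty_per_n=yty,
        xty_per_n=xty,
        cov_blocks=cov_blocks,
        cov_blocks_raw=cov_raw,
        s2=s2,
        rows=rows,
        N=problem.n_eff,
        reg=reg,
        panel_provenance=panel_half.provenance,
    )


def select_sigma2_subset(
    problem: HarmonizedProblem,
    panel_half: ReferencePanel,
    r2_max: float = 0.2,
    p_max: float = 1e-3,
    cap: int | None = None,
) -> np.ndarray:
    """Pruned-and-thresholded SNP set for the residual-variance estimate.

    Greedy clump at ``r^2 < r2_max`` (priority ascending p-value), keep
    p-values below ``p_max``, cap at ``min(500, N/4)`` SNPs. Returns problem
    row indices (possibly empty for a null trait).
    """
    d = problem.df
    if cap is None:
        cap = int(min(500, problem.n_eff // 4))
    rows = np.flatnonzero(problem.in_reference & (d["pvalue"].to_numpy() < p_max))
    if rows.size == 0:
        return rows
    lookup = {sid: j for j, sid in enumerate(panel_half.snps["snp_id"])}
    cols = np.array([lookup[sid] for sid in d["snp_id"].iloc[rows]])
    X = panel_half.imputed()[:, cols]
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = Xc / sd
    order = np.argsort(d["pvalue"].to_numpy()[rows], kind="mergesort")
    kept: list[int] = []
    for i in order:
        if len(kept) >= cap:
            break
        if kept:
            r = Xs[:, kept].T @ Xs[:, i] / Xs.shape[0]
            if np.any(r**2 >= r2_max):
                continue
        kept.append(i)
    return rows[np.sort(kept)]


def estimate_sigma2(
    moments: SummaryMoments, snp_subset: np.ndarray, q: int | None = None
) -> float:
    """Residual-variance estimate from the OLS fit on ``snp_subset``.

    ``snp_subset`` holds problem row indices; the regression reduction
    ``xty_S' Cov_S^{-1} xty_S`` is computed blockwise on the regularized
    covariance. ``q`` defaults to the subset size.
    """
    if q is None:
        q = len(snp_subset)
    if q >= moments.N:
        raise InputError("degrees of freedom q must be smaller than N")
    reduction = 0.0
    subset = set(int(r) for r in snp_subset)
    for pos, C in moments.cov_blocks:
        inblk = np.array([k for k, r in enumerate(moments.rows[pos]) if int(r) in subset])
        if inblk.size == 0:
            continue
        v = moments.xty_per_n[pos[inblk]]
        reduction += float(v @ np.linalg.solve(C[np.ix_(inblk, inblk)], v))
    value = moments.N / (moments.N - q) * (moments.yty_per_n - reduction)
    if value <= 0:
        raise InputError(
            "nonpositive residual-variance estimate; increase the covariance "
            "regularization or shrink the SNP subset"
        )
    return float(value)


def _centered_scale_weights(model: PRSModel, moments: SummaryMoments) -> np.ndarray:
    """Standardized betas converted to the centered-dosage scale."""
    return model.beta[moments.rows] * moments.sd_y / np.sqrt(moments.s2)


def estimate_sse(model: PRSModel, moments: SummaryMoments) -> float:
    """Estimated sum of squared errors of the PRS on the training data.

    ``SSE = N ( yty - 2 b' xty + b' Cov b )`` with ``b`` the model weights on
    the centered-dosage scale, computed blockwise with the regularized
    covariance (positive definite, so the quadratic form keeps SSE >= 0 for
    any weights).
    """
    if len(model.beta) <= moments.rows.max():
        raise InputError("model and moments refer to different problems")
    b = _centered_scale_weights(model, moments)
    quad = 0.0
    for pos, C in moments.cov_blocks:
        quad += float(b[pos] @ C @ b[pos])
    sse = moments.N * (moments.yty_per_n - 2.0 * float(b @ moments.xty_per_n) + quad)
    return float(sse)


def degrees_of_freedom(
    model: PRSModel,
    moments: SummaryMoments,
    mode: str = "ridge",
    lam_s: float | None = None,
) -> float:
    """Model degrees of freedom ``k``.

    ``mode="nonzero"``: count of nonzero weights. ``mode="ridge"``: blockwise
    ``tr[(R + lam*s I)^{-1} R]`` over the correlation submatrix of SNPs with
    nonzero weights (restricting to the active SNPs keeps the trace
    model-dependent), plus one per nonzero SNP outside the reference panel.
    ``lam_s`` defaults to ``penalty.lam * penalty.s``; a singular block at
    ``lam_s = 0`` falls back to the nonzero count with a warning.
    """
    if mode == "nonzero":
        return float(model.n_nonzero)
    if mode != "ridge":
        raise ConfigurationError(f"unknown df mode {mode!r}")
    if lam_s is None:
        lam_s = model.penalty.lam * model.penalty.s
    nz = model.beta != 0.0
    k = float(np.count_nonzero(np.delete(nz, moments.rows)))  # SNPs outside the panel
    s = np.sqrt(moments.s2)
    for pos, C in moments.cov_blocks_raw:
        active = np.flatnonzero(nz[moments.rows[pos]])
        if active.size == 0:
            continue
        sub = np.ix_(pos[active], pos[active])
        # correlation submatrix from the raw covariance
        Rsub = C[np.ix_(active, active)] / np.outer(s[pos[active]], s[pos[active]])
        eig = np.linalg.eigvalsh(Rsub)
        if lam_s == 0.0 and eig.min() < 1e-10:
            warnings.warn(
                "singular block with lam*s = 0: falling back to nonzero count",
                stacklevel=2,
            )
            k += active.size
        else:
            k += float(np.sum(eig / (eig + lam_s)))
    return k


@dataclass
class SelectionReport:
    """Per-candidate selection quantities and the chosen indices."""

    table: pd.DataFrame  # sse, sigma2, k, loglik, pseudo_aic, pseudo_bic, n_nonzero
    sigma2: float
    q: int
    selected_aic: int
    selected_bic: int

    def selected(self, criterion: str) -> int:
        return self.selected_aic if criterion == "aic" else self.selected_bic


def pseudo_criteria(
    models: list[PRSModel],
    moments: SummaryMoments,
    panel_half: ReferencePanel | None = None,
    problem: HarmonizedProblem | None = None,
    df_mode: str = "nonzero",
    sigma2: float | None = None,
    sigma2_subset: np.ndarray | None = None,
) -> SelectionReport:
    """Pseudo-AIC and pseudo-BIC for a set of candidate models.

    The residual variance is estimated once (from ``sigma2_subset``, or a
    default pruned-and-thresholded subset when ``panel_half`` and ``problem``
    are given) and shared across candidates. Ties in either criterion break
    toward the smaller degrees of freedom.
    """
    if not models:
        raise InputError("no candidate models")
    for m in models:
        if m.panel_provenance and m.panel_provenance == moments.panel_provenance:
            raise ProvenanceError(
                "models were fitted with the same panel half used for selection"
            )
    if sigma2 is None:
        if sigma2_subset is None:
            if panel_half is None or problem is None:
                raise ConfigurationError(
                    "provide sigma2, sigma2_subset, or panel_half+problem"
                )
            sigma2_subset = select_sigma2_subset(problem, panel_half)
        sigma2 = estimate_sigma2(moments, sigma2_subset)
        q = len(sigma2_subset)
    else:
        q = len(sigma2_subset) if sigma2_subset is not None else 0

    rows = []
    for m in models:
        sse = estimate_sse(m, moments)
        k = degrees_of_freedom(m, moments, mode=df_mode)
        loglik = -sse / (2.0 * sigma2)
        rows.append(
            {
                "sse": sse,
                "sigma2": sigma2,
                "k": k,
                "loglik": loglik,
                "pseudo_aic": 2.0 * k - 2.0 * loglik,
                "pseudo_bic": np.log(moments.N) * k - 2.0 * loglik,
                "n_nonzero": m.n_nonzero,
            }
        )
    table = pd.DataFrame(rows)

    def _argmin(col: str) -> int:
        order = sorted(range(len(models)), key=lambda i: (table[col][i], table["k"][i]))
        return order[0]

    return SelectionReport(
        table=table,
        sigma2=float(sigma2),
        q=int(q),
        selected_aic=_argmin("pseudo_aic"),
        selected_bic=_argmin("pseudo_bic"),
    )
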