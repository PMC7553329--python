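"""Penalized regression on GWAS summary statistics via blockwise coordinate descent.

Given SNP-phenotype correlations ``r`` and an LD matrix ``R`` estimated from
a reference panel, the fitted weights minimize, per LD block,

    f(beta) = (1 - s) beta' R beta + s beta' beta - 2 beta' r + J(beta)

where ``(1 - s) R + s I`` is the regularized LD matrix that keeps the problem
well posed, and ``J`` is one of

* LASSO:        J(beta) = 2 lambda * sum |beta_j|
* elastic net:  J(beta) = 2 alpha lambda * sum |beta_j| + (1 - alpha) lambda * sum beta_j^2
* TLP:          J(beta) = 2 lambda * sum min(|beta_j|, tau)

The factor 2 on the L1 part pairs with the unhalved quadratic so that the
identity-LD (s = 1) coordinate update is literally the soft threshold
``beta_j = S(r_j, lambda)`` — lambda is directly the threshold magnitude,
which keeps tuning grids interpretable. The truncated LASSO penalty (TLP)
stops penalizing coefficients above ``tau`` and is minimized by a
difference-of-convex outer loop around a weighted-LASSO inner solve.

SNPs absent from the reference panel are treated as mutually independent and
solved in closed form from the univariate objective ``beta^2 - 2 beta r + J``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .io import HarmonizedProblem, InputError, ConfigurationError, ReferencePanel

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltySpec",
    "PRSModel",
    "block_correlation",
    "fit_block",
    "fit_missing_snps",
    "fit_path",
    "rescale_to_per_allele",
    "predict_prs",
    "objective",
]

PENALTIES = ("lasso", "elastic_net", "tlp")


@dataclass(frozen=True)
class PenaltySpec:
    """A penalty family with its tuning parameters.

    ``lam`` is the soft-threshold magnitude, ``s`` the LD-regularization
    weight in ``(1-s) R + s I``, ``tau`` the TLP truncation point (may be
    ``inf``, which degenerates to LASSO), ``alpha`` the elastic-net mixing
    (1.0 degenerates to LASSO).
    """

    kind: str
    lam: float
    s: float = 0.1
    tau: float = np.inf
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in PENALTIES:
            raise ConfigurationError(f"unknown penalty kind {self.kind!r}")
        if self.lam < 0:
            raise ConfigurationError("lambda must be >= 0")
        if not (0 <= self.s <= 1):
            raise ConfigurationError("s must lie in [0, 1]")
        if self.kind == "tlp" and not self.tau > 0:
            raise ConfigurationError("tau must be > 0 for tlp")
        if self.kind == "elastic_net" and not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must lie in (0, 1] for elastic_net")

    def value(self, beta: np.ndarray) -> float:
        """J(beta) under this penalty (the additive term of the objective)."""
        a = np.abs(beta)
        if self.kind == "lasso":
            return 2.0 * self.lam * a.sum()
        if self.kind == "elastic_net":
            return 2.0 * self.alpha * self.lam * a.sum() + (1.0 - self.alpha) * self.lam * (
                beta**2
            ).sum()
        return 2.0 * self.lam * np.minimum(a, self.tau).sum()


def objective(beta: np.ndarray, r: np.ndarray, R: np.ndarray, penalty: PenaltySpec) -> float:
    """Blockwise objective value (the constant y'y term is omitted)."""
    s = penalty.s
    quad = (1.0 - s) * beta @ R @ beta + s * beta @ beta
    return float(quad - 2.0 * beta @ r + penalty.value(beta))


@dataclass
class PRSModel:
    """Fitted SNP weights on the standardized (correlation) scale.

    ``beta`` is aligned with the rows of the :class:`HarmonizedProblem` the
    model was fitted on. ``objective_value`` sums the blockwise objectives
    plus the univariate terms of SNPs outside the reference panel.
    """

    beta: np.ndarray
    penalty: PenaltySpec
    objective_value: float
    converged: bool = True
    n_iter: int = 0
    panel_provenance: str = ""
    block_diagnostics: list = field(default_factory=list)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))


def block_correlation(dosages: np.ndarray) -> np.ndarray:
    """Correlation matrix of one block's panel dosages (mean-imputed)."""
    X = np.asarray(dosages, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise InputError("need a 2-D dosage matrix with >= 1 SNP")
    if np.isnan(X).any():
        mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = mean[idx[1]]
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise InputError("zero-variance SNP in block (should have been filtered)")
    if X.shape[1] == 1:
        return np.ones((1, 1))
    R = np.corrcoef(X, rowvar=False)
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return R


@njit(cache=False)
def _cd_weighted_lasso(R, r, beta, one_minus_s, thresh, l2, tol, max_iter):  # pragma: no cover
    """Cyclic coordinate descent for a (weighted) LASSO / elastic-net block.

    ``thresh`` is the per-coordinate soft-threshold, ``l2`` the extra ridge
    coefficient from the elastic net. Maintains R @ beta incrementally.
    Returns (sweeps used, converged flag).
    """
    p = beta.shape[0]
    Rb = R @ beta
    denom = 1.0 + l2
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            z = r[j] - one_minus_s * (Rb[j] - beta[j])
            az = abs(z) - thresh[j]
            if az > 0.0:
                new = (az if z > 0.0 else -az) / denom
            else:
                new = 0.0
            d = new - beta[j]
            if d != 0.0:
                for i in range(p):
                    Rb[i] += R[i, j] * d
                beta[j] = new
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            return it + 1, True
    return max_iter, False


def _solve_convex(
    r: np.ndarray,
    R: np.ndarray,
    penalty: PenaltySpec,
    thresh: np.ndarray,
    init: np.ndarray | None,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, bool]:
    beta = np.zeros_like(r) if init is None else np.array(init, dtype=float)
    l2 = (1.0 - penalty.alpha) * penalty.lam if penalty.kind == "elastic_net" else 0.0
    iters, ok = _cd_weighted_lasso(
        np.ascontiguousarray(R, dtype=float),
        np.ascontiguousarray(r, dtype=float),
        beta,
        1.0 - penalty.s,
        np.ascontiguousarray(thresh, dtype=float),
        l2,
        tol,
        max_iter,
    )
    return beta, int(iters), bool(ok)


def fit_block(
    r: np.ndarray,
    R: np.ndarray,
    penalty: PenaltySpec,
    init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    tlp_outer_max: int = 50,
    tlp_exact_max: int = 8,
) -> tuple[np.ndarray, dict]:
    """Minimize the blockwise objective for one LD block.

    LASSO and elastic net use cyclic coordinate descent. TLP on blocks of up
    to ``tlp_exact_max`` SNPs is solved exactly by enumerating the binary
    weight patterns of its variational form (each pattern a convex weighted
    LASSO). Larger blocks run a difference-of-convex loop: coefficients with
    ``|beta_j| <= tau`` keep the full L1 threshold (weight 1) and the rest
    are unpenalized (weight 0); the weighted LASSO is re-solved until the
    weight set stabilizes. The DC loop is run from two starts — the LASSO
    solution at the same ``(lam, s)`` and the unpenalized solution — and the
    better local minimum is kept; the TLP objective is non-increasing across
    outer iterations by the standard majorize-minimize argument.

    Returns ``(beta, diagnostics)``; non-convergence sets
    ``diagnostics["converged"] = False`` rather than raising.
    """
    r = np.asarray(r, dtype=float)
    R = np.asarray(R, dtype=float)
    if r.ndim != 1 or R.shape != (len(r), len(r)):
        raise InputError("dimension mismatch between r and R")
    if np.isnan(r).any() or np.isnan(R).any():
        raise InputError("NaN in fitting inputs")

    lam = penalty.lam
    if penalty.kind == "lasso" or (penalty.kind == "tlp" and np.isinf(penalty.tau)):
        thresh = np.full(len(r), lam)
        eff = replace(penalty, kind="lasso", tau=np.inf, alpha=1.0)
        beta, iters, ok = _solve_convex(r, R, eff, thresh, init, tol, max_iter)
        diag = {"iterations": iters, "converged": ok, "outer_iterations": 0}
    elif penalty.kind == "elastic_net":
        thresh = np.full(len(r), penalty.alpha * lam)
        beta, iters, ok = _solve_convex(r, R, penalty, thresh, init, tol, max_iter)
        diag = {"iterations": iters, "converged": ok, "outer_iterations": 0}
    elif len(r) <= tlp_exact_max:
        # small blocks: exact global minimum by enumerating the binary weight
        # patterns of min(|b|, tau) = min_w [w |b| + (1 - w) tau]; each pattern
        # is a convex weighted LASSO
        lasso = replace(penalty, kind="lasso", tau=np.inf, alpha=1.0)
        best, best_obj, total, ok = None, np.inf, 0, True
        beta = None
        for pattern in range(2 ** len(r)):
            w = np.array([(pattern >> j) & 1 for j in range(len(r))], dtype=float)
            beta, iters, ok_i = _solve_convex(r, R, lasso, lam * w, beta, tol, max_iter)
            total += iters
            ok = ok and ok_i
            obj = objective(beta, r, R, penalty)
            if obj < best_obj:
                best_obj, best = obj, beta.copy()
        beta = best
        diag = {"iterations": total, "converged": ok, "outer_iterations": 0}
    else:  # tlp on a large block: difference-of-convex, two starts
        lasso = replace(penalty, kind="lasso", tau=np.inf, alpha=1.0)
        b_lasso, it0, ok0 = _solve_convex(r, R, lasso, np.full(len(r), lam), init, tol, max_iter)
        b_free, it1, ok1 = _solve_convex(r, R, lasso, np.zeros(len(r)), init, tol, max_iter)
        total, ok = it0 + it1, ok0 and ok1
        best, best_obj, worst_outer = None, np.inf, 0
        for start in (b_lasso, b_free):
            beta = start.copy()
            weights = np.abs(beta) <= penalty.tau
            outer = 0
            for outer in range(1, tlp_outer_max + 1):
                beta, iters, ok_i = _solve_convex(
                    r, R, lasso, lam * weights.astype(float), beta, tol, max_iter
                )
                total += iters
                ok = ok and ok_i
                new_weights = np.abs(beta) <= penalty.tau
                if np.array_equal(new_weights, weights):
                    break
                weights = new_weights
            worst_outer = max(worst_outer, outer)
            obj = objective(beta, r, R, penalty)
            if obj < best_obj:
                best_obj, best = obj, beta
        beta = best
        diag = {"iterations": total, "converged": ok, "outer_iterations": worst_outer}
    diag["objective"] = objective(beta, r, R, penalty)
    if not diag["converged"]:
        logger.warning("block of %d SNPs did not converge (%s)", len(r), penalty)
    return beta, diag


def _univariate_tlp(r: float, lam: float, tau: float) -> float:
    """Exact minimizer of beta^2 - 2 beta r + 2 lam min(|beta|, tau)."""

    def g(b: float) -> float:
        return b * b - 2.0 * b * r + 2.0 * lam * min(abs(b), tau)

    sgn = 1.0 if r >= 0 else -1.0
    soft = sgn * max(abs(r) - lam, 0.0)
    # best point in the penalized region |beta| <= tau
    cand_in = sgn * min(abs(soft), tau)
    # best point in the flat region |beta| >= tau
    cand_out = r if abs(r) >= tau else sgn * tau
    return cand_in if g(cand_in) <= g(cand_out) else cand_out


def fit_missing_snps(r_values: np.ndarray, penalty: PenaltySpec) -> np.ndarray:
    """Closed-form weights for SNPs absent from the reference panel.

    Such SNPs are treated as mutually independent, so each solves the
    univariate objective ``beta^2 - 2 beta r + J(beta)`` exactly (the ``s``
    and ``1 - s`` diagonal contributions sum to one).
    """
    r = np.asarray(r_values, dtype=float)
    lam = penalty.lam
    if penalty.kind == "lasso" or (penalty.kind == "tlp" and np.isinf(penalty.tau)):
        return np.sign(r) * np.maximum(np.abs(r) - lam, 0.0)
    if penalty.kind == "elastic_net":
        soft = np.sign(r) * np.maximum(np.abs(r) - penalty.alpha * lam, 0.0)
        return soft / (1.0 + (1.0 - penalty.alpha) * lam)
    return np.array([_univariate_tlp(ri, lam, penalty.tau) for ri in r])


def _missing_objective(beta: np.ndarray, r: np.ndarray, penalty: PenaltySpec) -> float:
    return float(beta @ beta - 2.0 * beta @ r + penalty.value(beta))


def block_matrices(
    problem: HarmonizedProblem, panel: ReferencePanel
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-block (row positions, correlation matrix) pairs from the panel."""
    X = panel.imputed()
    out = []
    for _, rows in problem.block_groups():
        cols = problem.df["panel_col"].to_numpy()[rows]
        out.append((rows, block_correlation(X[:, cols])))
    return out


def fit_path(
    problem: HarmonizedProblem,
    panel: ReferencePanel,
    grid: list[PenaltySpec],
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> list[PRSModel]:
    """Fit every penalty in ``grid``, blockwise, with warm starts.

    Within each ``(kind, s, tau, alpha)`` slice the grid is solved in order
    of descending lambda, each solution warm-starting the next. Models are
    returned in the original grid order. A failure in one block aborts that
    grid point only (logged); the model list then skips that entry.
    """
    if not grid:
        raise ConfigurationError("empty penalty grid")
    blocks = block_matrices(problem, panel)
    r_all = problem.r
    missing_rows = np.flatnonzero(~problem.in_reference)

    results: dict[int, PRSModel] = {}
    order = sorted(
        range(len(grid)),
        key=lambda i: (grid[i].kind, grid[i].s, grid[i].tau, grid[i].alpha, -grid[i].lam),
    )
    warm: dict[tuple, list[np.ndarray]] = {}
    for gi in order:
        pen = grid[gi]
        key = (pen.kind, pen.s, pen.tau, pen.alpha)
        inits = warm.get(key)
        beta = np.zeros(len(problem.df))
        total_obj = 0.0
        converged = True
        n_iter = 0
        diags = []
        new_inits = []
        try:
            for bi, (rows, R) in enumerate(blocks):
                init = inits[bi] if inits is not None else None
                b, diag = fit_block(r_all[rows], R, pen, init=init, tol=tol, max_iter=max_iter)
                beta[rows] = b
                total_obj += diag["objective"]
                converged &= diag["converged"]
                n_iter = max(n_iter, diag["iterations"])
                diags.append(diag)
                new_inits.append(b)
        except InputError as exc:
            logger.warning("grid point %s failed: %s", pen, exc)
            continue
        if missing_rows.size:
            bm = fit_missing_snps(r_all[missing_rows], pen)
            beta[missing_rows] = bm
            total_obj += _missing_objective(bm, r_all[missing_rows], pen)
        warm[key] = new_inits
        results[gi] = PRSModel(
            beta=beta,
            penalty=pen,
            objective_value=total_obj,
            converged=converged,
            n_iter=n_iter,
            panel_provenance=panel.provenance,
            block_diagnostics=diags,
        )
    return [results[i] for i in sorted(results)]


def rescale_to_per_allele(
    model: PRSModel, problem: HarmonizedProblem, sd_y: float | None = None
) -> pd.DataFrame:
    """Per-allele weights ``beta_j * sd(y) / s_hat_j`` for scoring raw dosages.

    SNPs without a usable panel SD (absent from the panel, or zero variance)
    are excluded. ``sd_y`` defaults to the moment-based estimate stored on
    the problem; pass it explicitly for traits with known phenotype SD.
    """
    if sd_y is None:
        sd_y = problem.sd_y_hat
    if sd_y is None or not np.isfinite(sd_y) or sd_y <= 0:
        raise InputError(
            "no phenotype SD available: provide sd_y or use standardized weights"
        )
    d = problem.df
    s = d["s_hat"].to_numpy()
    usable = np.isfinite(s) & (s > 0)
    out = d.loc[usable, ["snp_id", "a1"]].copy()
    out["standardized_beta"] = model.beta[usable]
    out["per_allele_beta"] = model.beta[usable] * sd_y / s[usable]
    return out.reset_index(drop=True)


def predict_prs(
    weights: pd.DataFrame | np.ndarray,
    genotypes: ReferencePanel | np.ndarray,
    snp_ids: list[str] | None = None,
    column: str = "per_allele_beta",
) -> np.ndarray:
    """Linear score ``score_i = sum_j x_ij w_j`` with mean-imputed dosages.

    ``weights`` is either the frame from :func:`rescale_to_per_allele`
    (matched to the genotypes by ``snp_id``) or a plain vector aligned with
    the genotype columns. Unmatched SNP ids raise, listing the offenders.
    """
    if isinstance(genotypes, ReferencePanel):
        X = genotypes.imputed()
        ids = list(genotypes.snps["snp_id"])
    else:
        X = np.asarray(genotypes, dtype=float)
        if np.isnan(X).any():
            mean = np.nanmean(X, axis=0)
            idx = np.where(np.isnan(X))
            X = X.copy()
            X[idx] = mean[idx[1]]
        ids = snp_ids

    if isinstance(weights, pd.DataFrame):
        if ids is None:
            raise InputError("snp_ids required to match weight table to genotypes")
        lookup = {sid: j for j, sid in enumerate(ids)}
        missing = [sid for sid in weights["snp_id"] if sid not in lookup]
        if missing:
            raise InputError(f"weights reference SNPs absent from genotypes: {missing[:5]}")
        cols = np.array([lookup[sid] for sid in weights["snp_id"]])
        w = weights[column].to_numpy()
        return X[:, cols] @ w
    w = np.asarray(weights, dtype=float)
    if len(w) != X.shape[1]:
        raise InputError("weight vector length does not match genotype columns")
    return X @ w
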