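"""Synthetic GWAS data: block-LD genotypes, causal effects, phenotypes, summary stats.

The generator emulates the structure the downstream methods assume:

* genotypes with block-diagonal LD — within each block two latent AR(1)
  standard-normal haplotypes per individual are thresholded at the MAF
  quantile and summed, so Hardy-Weinberg equilibrium holds by construction
  and LD decays geometrically with distance inside a block;
* causal effects from a point-normal model (a fixed number ``round(p * M)``
  of causal SNPs with N(0, h2 / m_causal) effects on the standardized scale)
  or a clustered variant where causal SNPs come in groups of 2-8 SNPs
  sharing a block and in mutual LD — an emulation of allelic heterogeneity;
* additive quantitative phenotypes with noise calibrated so the genetic
  variance fraction matches the target heritability, or binary phenotypes
  via a liability threshold;
* marginal per-SNP GWAS summary statistics (OLS for quantitative traits,
  per-SNP logistic ML for binary traits).

Disjoint cohort splits (train / tune1 / tune2 / test) are drawn independently
from the same LD process, mirroring the standard four-way design in which
training summary statistics, the fitting reference panel, the selection
reference panel, and the evaluation data are all distinct samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import (
    ConfigurationError,
    InputError,
    LDBlockSet,
    ReferencePanel,
    SummaryStats,
    blocks_from_sizes,
)

__all__ = [
    "SimConfig",
    "SimStudy",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotype",
    "compute_gwas",
    "simulate_study",
]

#: split sizes used throughout: training summary statistics, fitting panel,
#: selection panel, evaluation cohort
DEFAULT_SPLITS = {"train": 6240, "tune1": 3119, "tune2": 1560, "test": 1560}


@dataclass
class SimConfig:
    """Parameters of a simulated GWAS study.

    ``h2`` is SNP heritability, ``p_causal`` the causal fraction of the
    ``n_snps`` SNPs, ``within_block_rho`` the AR(1) correlation of the latent
    haplotype normals inside a block (LD between adjacent SNPs), and
    ``block_sizes`` the SNP count per LD block (defaults to blocks of 50).
    """

    n_snps: int = 2000
    splits: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SPLITS))
    block_sizes: list[int] | None = None
    within_block_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.5
    p_causal: float = 0.01
    effect_model: str = "point_normal"  # or "clustered"
    cluster_size_range: tuple[int, int] = (2, 8)
    cluster_r2_min: float = 0.25
    binary: bool = False
    case_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_sizes is None:
            size = min(50, self.n_snps)
            n_full, rem = divmod(self.n_snps, size)
            self.block_sizes = [size] * n_full + ([rem] if rem else [])
        if sum(self.block_sizes) != self.n_snps:
            raise ConfigurationError("block sizes must sum to n_snps")
        if not (0 <= self.within_block_rho < 1):
            raise ConfigurationError("within_block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.h2 < 1):
            raise ConfigurationError("h2 must lie in [0, 1)")
        if not (0 < self.p_causal <= 1):
            raise ConfigurationError("p_causal must lie in (0, 1]")


@dataclass
class SimStudy:
    """Realized simulation: genotypes and phenotypes per split, plus the truth."""

    cfg: SimConfig
    genotypes: dict[str, np.ndarray]
    phenotypes: dict[str, np.ndarray]
    beta: np.ndarray  # standardized scale
    causal: np.ndarray  # indices
    realized_h2: float
    mafs: np.ndarray
    snps: pd.DataFrame
    blocks: LDBlockSet

    def panel(self, split: str, provenance: str | None = None) -> ReferencePanel:
        return ReferencePanel(
            self.genotypes[split].astype(float),
            self.snps.copy(),
            provenance=provenance or f"sim:{split}",
        )


def _snp_metadata(n_snps: int) -> pd.DataFrame:
    width = len(str(n_snps))
    return pd.DataFrame(
        {
            "snp_id": [f"snp{j:0{width}d}" for j in range(n_snps)],
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1),
            "a1": "A",
            "a2": "G",
        }
    )


def _ar1(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """n x m matrix of AR(1) standard normals along the second axis."""
    z = rng.standard_normal((n, m))
    if rho == 0 or m == 1:
        return z
    scale = np.sqrt(1.0 - rho**2)
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    for k in range(1, m):
        out[:, k] = rho * out[:, k - 1] + scale * z[:, k]
    return out


def simulate_genotypes(
    cfg: SimConfig, n: int, mafs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw an n x M dosage matrix with block-AR(1) latent LD.

    Two independent latent haplotypes per individual are thresholded at the
    per-SNP MAF quantile (allele present iff latent normal exceeds the upper
    ``maf`` quantile) and summed, giving dosages in {0, 1, 2} under HWE.
    """
    thr = _stats.norm.isf(mafs)
    X = np.empty((n, cfg.n_snps), dtype=np.int8)
    start = 0
    for size in cfg.block_sizes:
        sl = slice(start, start + size)
        h1 = _ar1(rng, n, size, cfg.within_block_rho) > thr[sl]
        h2 = _ar1(rng, n, size, cfg.within_block_rho) > thr[sl]
        X[:, sl] = h1.astype(np.int8) + h2.astype(np.int8)
        start += size
    return X


def simulate_effects(
    cfg: SimConfig, rng: np.random.Generator, genotypes: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw standardized-scale causal effects.

    Point-normal: exactly ``m = round(p_causal * n_snps)`` causal SNPs chosen
    without replacement, effects N(0, h2 / m) so the genetic variance targets
    ``h2``. Clustered: causal SNPs come in groups of ``cluster_size_range``
    members sharing a block, each group member in LD (r^2 >=
    ``cluster_r2_min``) with the group's anchor SNP; requires ``genotypes``
    to measure LD. Returns ``(beta, causal_indices)``.
    """
    m_target = int(round(cfg.p_causal * cfg.n_snps))
    if m_target < 1:
        raise ConfigurationError("p_causal * n_snps rounds to zero causal SNPs")

    if cfg.effect_model == "point_normal":
        causal = np.sort(rng.choice(cfg.n_snps, size=m_target, replace=False))
    elif cfg.effect_model == "clustered":
        if genotypes is None:
            raise ConfigurationError("clustered effects need genotypes to measure LD")
        causal = _clustered_causal_set(cfg, rng, genotypes, m_target)
    else:
        raise ConfigurationError(f"unknown effect model {cfg.effect_model!r}")

    beta = np.zeros(cfg.n_snps)
    beta[causal] = rng.standard_normal(len(causal)) * np.sqrt(cfg.h2 / len(causal))
    return beta, causal


def _clustered_causal_set(
    cfg: SimConfig, rng: np.random.Generator, X: np.ndarray, m_target: int
) -> np.ndarray:
    lo, hi = cfg.cluster_size_range
    edges = np.concatenate([[0], np.cumsum(cfg.block_sizes)])
    block_of = np.searchsorted(edges, np.arange(cfg.n_snps), side="right") - 1

    Xs = X.astype(float)
    Xs -= Xs.mean(axis=0)
    sd = Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Xs /= sd

    # neighbors with r^2 >= threshold inside the same block, per SNP
    neighbors: dict[int, np.ndarray] = {}
    for b in range(len(cfg.block_sizes)):
        sl = slice(edges[b], edges[b + 1])
        r2 = (Xs[:, sl].T @ Xs[:, sl] / X.shape[0]) ** 2
        np.fill_diagonal(r2, 0.0)
        for k in range(r2.shape[0]):
            nb = np.flatnonzero(r2[k] >= cfg.cluster_r2_min) + edges[b]
            if nb.size:
                neighbors[edges[b] + k] = nb
    anchors_avail = np.array(sorted(neighbors), dtype=np.int64)
    if anchors_avail.size == 0:
        raise ConfigurationError(
            "clustered effects infeasible: no SNP has an in-block neighbor with "
            f"r^2 >= {cfg.cluster_r2_min} (blocks too small or LD too weak)"
        )

    causal: set[int] = set()
    rng.shuffle(anchors_avail)
    for anchor in anchors_avail:
        remaining = m_target - len(causal)
        if remaining < 2:
            break  # never create a singleton group
        if anchor in causal:
            continue
        pool = [j for j in neighbors[anchor] if j not in causal]
        if not pool:
            continue
        group_size = int(rng.integers(lo, hi + 1))
        take = min(group_size - 1, len(pool), remaining - 1)
        group = [int(anchor)] + [int(j) for j in rng.permutation(pool)[:take]]
        causal.update(group)
    if len(causal) < min(2, m_target):
        raise ConfigurationError("clustered effects infeasible: could not form any group")
    return np.sort(np.fromiter(causal, dtype=np.int64))


def simulate_phenotype(
    genotypes: np.ndarray,
    beta: np.ndarray,
    h2: float,
    rng: np.random.Generator,
    noise_sd: float | None = None,
    binary: bool = False,
    case_fraction: float = 0.5,
) -> np.ndarray:
    """Additive phenotype ``y = X_std beta + eps`` on standardized genotypes.

    When ``noise_sd`` is None the noise variance is set from the empirical
    genetic variance so var(genetic) / var(y) targets ``h2``. Binary traits
    threshold the liability at the empirical ``1 - case_fraction`` quantile.
    """
    g = _genetic_values(genotypes, beta)
    if h2 == 0:
        if np.any(beta != 0):
            raise ConfigurationError("h2 = 0 is inconsistent with nonzero effects")
        y = rng.standard_normal(len(g))
    else:
        if noise_sd is None:
            var_g = g.var()
            noise_sd = np.sqrt(var_g * (1.0 - h2) / h2) if var_g > 0 else 1.0
        y = g + rng.normal(0.0, noise_sd, size=len(g))
    if binary:
        thr = np.quantile(y, 1.0 - case_fraction)
        return (y > thr).astype(np.int8)
    return y


def _genetic_values(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(beta)
    Xc = X[:, nz].astype(float)
    Xc -= Xc.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    return (Xc / sd) @ beta[nz]


def compute_gwas(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    snps: pd.DataFrame | None = None,
    binary: bool = False,
    se_method: str = "ols",
) -> SummaryStats:
    """Per-SNP marginal association scan.

    Quantitative traits: simple OLS slope per SNP. ``se_method="ols"`` uses
    the classic residual variance with n-2 degrees of freedom and a t-test;
    ``se_method="ml"`` uses ``var(beta) = RSS / (N^2 s^2)`` with a normal
    test — the moment convention under which the summary-statistic identities
    for (1/N) Y'Y and (1/N) X'Y are exact. Binary traits: per-SNP logistic
    regression (intercept + dosage) fit by Newton iterations. Monomorphic
    SNPs are excluded.
    """
    X = genotypes.astype(float)
    y = np.asarray(phenotype, dtype=float)
    n, p = X.shape
    if snps is None:
        snps = _snp_metadata(p)
    keep = X.std(axis=0) > 0
    if not keep.any():
        raise InputError("all SNPs monomorphic")

    if binary:
        beta, se, pval = _logistic_scan(X[:, keep], y)
    else:
        xc = X[:, keep] - X[:, keep].mean(axis=0)
        yc = y - y.mean()
        sxx = (xc**2).sum(axis=0)
        syy = float((yc**2).sum())
        beta = xc.T @ yc / sxx
        rss = np.maximum(syy - beta**2 * sxx, 0.0)
        if se_method == "ols":
            se = np.sqrt(rss / (n - 2) / sxx)
            pval = 2.0 * _stats.t.sf(np.abs(beta / se), df=n - 2)
        elif se_method == "ml":
            se = np.sqrt(rss / (n * sxx))
            pval = 2.0 * _stats.norm.sf(np.abs(beta / se))
        else:
            raise ConfigurationError(f"unknown se_method {se_method!r}")

    df = snps.loc[keep].reset_index(drop=True).copy()
    df["beta"] = beta
    df["se"] = se
    df["n"] = n
    df["pvalue"] = np.clip(pval, np.finfo(float).tiny, 1.0)
    return SummaryStats(df, is_binary_trait=binary)


def _logistic_scan(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP logistic regression (intercept + one SNP) by Newton."""
    n, p = X.shape
    b0 = np.full(p, _logit(np.clip(y.mean(), 1e-12, 1 - 1e-12)))
    b1 = np.zeros(p)
    for _ in range(max_iter):
        eta = b0[None, :] + X * b1[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu
        g0 = resid.sum(axis=0)
        g1 = (X * resid).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * X).sum(axis=0)
        h11 = (w * X**2).sum(axis=0)
        det = h00 * h11 - h01**2
        det = np.where(det <= 0, np.nan, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        b0 += np.nan_to_num(d0)
        b1 += np.nan_to_num(d1)
        if max(np.nanmax(np.abs(d0), initial=0), np.nanmax(np.abs(d1), initial=0)) < tol:
            break
    eta = b0[None, :] + X * b1[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    h00 = w.sum(axis=0)
    h01 = (w * X).sum(axis=0)
    h11 = (w * X**2).sum(axis=0)
    var_b1 = h00 / np.maximum(h00 * h11 - h01**2, np.finfo(float).tiny)
    se = np.sqrt(var_b1)
    pval = 2.0 * _stats.norm.sf(np.abs(b1 / se))
    return b1, se, pval


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def simulate_study(cfg: SimConfig, se_method: str = "ols") -> SimStudy:
    """Run the full generator: genotypes, effects, phenotypes for every split.

    The noise SD is calibrated once on the training split and reused for all
    splits, so each cohort is an independent draw from the same trait model.
    """
    rng = np.random.default_rng(cfg.seed)
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    snps = _snp_metadata(cfg.n_snps)
    blocks = blocks_from_sizes(cfg.block_sizes)

    genotypes = {
        name: simulate_genotypes(cfg, n, mafs, rng) for name, n in cfg.splits.items()
    }
    first = next(iter(genotypes))
    beta, causal = simulate_effects(cfg, rng, genotypes=genotypes[first])

    if cfg.h2 > 0:
        g_train = _genetic_values(genotypes[first], beta)
        noise_sd = float(np.sqrt(g_train.var() * (1.0 - cfg.h2) / cfg.h2))
    else:
        noise_sd = 1.0
    phenotypes = {
        name: simulate_phenotype(
            X, beta, cfg.h2, rng, noise_sd=noise_sd,
            binary=cfg.binary, case_fraction=cfg.case_fraction,
        )
        for name, X in genotypes.items()
    }

    if cfg.h2 > 0 and not cfg.binary:
        g = _genetic_values(genotypes[first], beta)
        realized = float(g.var() / phenotypes[first].var())
    else:
        realized = float("nan")
    return SimStudy(
        cfg=cfg,
        genotypes=genotypes,
        phenotypes=phenotypes,
        beta=beta,
        causal=causal,
        realized_h2=realized,
        mafs=mafs,
        snps=snps,
        blocks=blocks,
    )
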