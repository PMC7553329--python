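"""Reading, writing and harmonizing summary statistics, reference panels and LD blocks.

The module aligns three inputs into a single :class:`HarmonizedProblem`:

* GWAS summary statistics (per-SNP marginal effect, SE, sample size, p-value),
* a genotype reference panel (PLINK-1 bed/bim/fam) used to estimate allele
  frequencies and linkage disequilibrium,
* a set of approximately independent LD blocks (3-column BED intervals).

Harmonization intersects SNPs by id, resolves effect-allele orientation,
removes strand-ambiguous (A/T, C/G) variants, filters on panel MAF, greedily
clumps SNPs in very high LD, and converts marginal effects to SNP-phenotype
correlations ``r`` — the quantity the penalized-regression objective consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "PrsumError",
    "ConfigurationError",
    "InputError",
    "FormatError",
    "ProvenanceError",
    "SummaryStats",
    "ReferencePanel",
    "LDBlockSet",
    "HarmonizedProblem",
    "read_sumstats",
    "write_sumstats",
    "read_reference_panel",
    "write_reference_panel",
    "load_ld_blocks",
    "harmonize",
]


class PrsumError(Exception):
    """Base class for package errors."""


class ConfigurationError(PrsumError):
    """A configuration (column map, parameter) problem."""


class InputError(PrsumError):
    """The input data is unusable (empty, inconsistent, misaligned)."""


class FormatError(PrsumError):
    """A file does not conform to its declared format."""


class ProvenanceError(PrsumError):
    """A reference-panel half is being reused where independence is required."""


#: default column names for summary-statistics files
DEFAULT_COLUMNS = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "beta": "BETA",
    "se": "SE",
    "n": "N",
    "pvalue": "P",
}

#: strand-ambiguous (palindromic) allele pairs
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SummaryStats:
    """Per-SNP marginal GWAS results.

    ``df`` holds canonical columns ``snp_id, chrom, pos, a1, a2, beta, se, n,
    pvalue``; ``a1`` is the effect allele. ``beta`` is per-allele, in trait
    units for quantitative traits or log-odds for binary traits.
    """

    df: pd.DataFrame
    is_binary_trait: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        d = self.df
        required = ["snp_id", "a1", "a2", "beta", "se", "n"]
        missing = [c for c in required if c not in d.columns]
        if missing:
            raise ConfigurationError(f"summary statistics missing columns: {missing}")
        if len(d) == 0:
            raise InputError("summary statistics are empty")
        if not (d["se"] > 0).all():
            raise InputError("all standard errors must be > 0")
        if not (d["n"] >= 2).all():
            raise InputError("per-SNP sample size must be >= 2")
        if d["snp_id"].duplicated().any():
            dup = d.loc[d["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise InputError(f"duplicate snp_id: {dup!r}")
        if (d["a1"] == d["a2"]).any():
            raise InputError("a1 == a2 for some SNP")
        if "pvalue" not in d.columns:
            z = d["beta"] / d["se"]
            d = d.assign(pvalue=2.0 * _stats.norm.sf(np.abs(z)))
            self.df = d

    def __len__(self) -> int:
        return len(self.df)


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    n: float | None = None,
    is_binary_trait: bool = False,
) -> SummaryStats:
    """Read a whitespace/TSV summary-statistics file.

    Parameters
    ----------
    column_map
        Maps canonical names (keys of :data:`DEFAULT_COLUMNS`) to the file's
        header names; unspecified entries fall back to the defaults.
    n
        Global sample size, used when the file lacks an N column.

    Rows whose beta or SE fail to parse as numbers are dropped with a logged
    count; missing optional columns (chrom, pos, pvalue) are tolerated.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    try:
        raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty summary-statistics file: {path}") from None
    if len(raw) == 0:
        raise InputError(f"no data rows in summary-statistics file: {path}")

    mandatory = ["snp_id", "a1", "a2", "beta", "se"]
    for key in mandatory:
        if cmap[key] not in raw.columns:
            raise ConfigurationError(
                f"mandatory column {cmap[key]!r} (for {key}) not found in {path}"
            )
    out = pd.DataFrame({"snp_id": raw[cmap["snp_id"]].astype(str)})
    for key in ("chrom", "pos"):
        if cmap[key] in raw.columns:
            col = raw[cmap[key]]
            out[key] = col.astype(str) if key == "chrom" else pd.to_numeric(col, errors="coerce")
    out["a1"] = raw[cmap["a1"]].str.upper()
    out["a2"] = raw[cmap["a2"]].str.upper()
    for key in ("beta", "se", "pvalue"):
        if cmap[key] in raw.columns:
            out[key] = pd.to_numeric(raw[cmap[key]], errors="coerce")
    if cmap["n"] in raw.columns:
        out["n"] = pd.to_numeric(raw[cmap["n"]], errors="coerce")
    elif n is not None:
        out["n"] = float(n)
    else:
        raise ConfigurationError(
            f"no sample-size column {cmap['n']!r} in {path} and no global n given"
        )

    bad = out["beta"].isna() | out["se"].isna() | out["n"].isna()
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("dropping %d rows with non-numeric beta/se/n", n_bad)
        out = out.loc[~bad]
    if len(out) == 0:
        raise InputError(f"all rows dropped while parsing {path}")
    return SummaryStats(out.reset_index(drop=True), is_binary_trait=is_binary_trait, n_dropped=n_bad)


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    """Write summary statistics with the default header names, tab-separated."""
    inv = {v: k for k, v in DEFAULT_COLUMNS.items()}
    cols = [c for c in DEFAULT_COLUMNS if c in ss.df.columns]
    d = ss.df[cols].rename(columns={k: v for v, k in inv.items()})
    d.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK-1 bed/bim/fam


@dataclass
class ReferencePanel:
    """A genotype panel used to estimate LD and allele frequencies.

    ``genotypes`` is an ``n_ref x p`` float matrix of counts of the ``a1``
    allele in {0, 1, 2}, with ``NaN`` marking missing calls. ``snps`` carries
    per-SNP metadata (``snp_id, chrom, pos, a1, a2``) in column order.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    provenance: str = "panel"

    def __post_init__(self) -> None:
        if self.genotypes.ndim != 2:
            raise InputError("genotypes must be 2-D (individuals x SNPs)")
        if self.genotypes.shape[1] != len(self.snps):
            raise InputError("genotype columns do not match SNP metadata rows")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.genotypes, initial=0) < 0 or np.nanmax(self.genotypes, initial=0) > 2:
                raise InputError("dosages must lie in [0, 2]")
        if np.isnan(self.genotypes).all(axis=0).any():
            raise InputError("some SNP has 100% missing genotypes")

    @property
    def n_ref(self) -> int:
        return self.genotypes.shape[0]

    @property
    def p(self) -> int:
        return self.genotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the a1 allele per SNP (missing calls ignored)."""
        return np.nanmean(self.genotypes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the per-SNP mean."""
        g = self.genotypes
        if not np.isnan(g).any():
            return g.astype(float, copy=False)
        mean = np.nanmean(g, axis=0)
        out = np.array(g, dtype=float)
        idx = np.where(np.isnan(out))
        out[idx] = mean[idx[1]]
        return out

    def sd(self) -> np.ndarray:
        """Per-SNP dosage standard deviation after mean imputation (ddof=0)."""
        return self.imputed().std(axis=0)

    def subset(self, cols: np.ndarray, provenance: str | None = None) -> "ReferencePanel":
        return ReferencePanel(
            self.genotypes[:, cols],
            self.snps.iloc[np.asarray(cols)].reset_index(drop=True),
            provenance=provenance or self.provenance,
        )

    def take_individuals(self, rows: np.ndarray, provenance: str) -> "ReferencePanel":
        return ReferencePanel(self.genotypes[rows], self.snps.copy(), provenance=provenance)


# 2-bit PLINK codes per genotype: 00 -> 2 copies of a1, 01 -> missing,
# 10 -> het, 11 -> 0 copies.  Table maps byte -> 4 dosages (NaN missing).
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_BYTE_TABLE = np.empty((256, 4))
for _b in range(256):
    for _k in range(4):
        _BYTE_TABLE[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]


def read_reference_panel(plink_prefix: str | Path) -> ReferencePanel:
    """Read a PLINK-1 bed/bim/fam triplet (SNP-major bed)."""
    prefix = Path(plink_prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FormatError(f"missing {prefix.with_suffix(ext)}")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if len(raw) < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise FormatError(f"{prefix.with_suffix('.bed')}: bad magic bytes")
    if raw[2] != 0x01:
        raise FormatError("only SNP-major bed files are supported")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * p
    if len(raw) != expected:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: expected {expected} bytes "
            f"({p} SNPs x {bytes_per_snp} bytes + 3), found {len(raw)}"
        )
    body = raw[3:].reshape(p, bytes_per_snp)
    dosages = _BYTE_TABLE[body].reshape(p, bytes_per_snp * 4)[:, :n]
    snps = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    return ReferencePanel(np.ascontiguousarray(dosages.T), snps, provenance=str(prefix))


def write_reference_panel(panel: ReferencePanel, plink_prefix: str | Path) -> None:
    """Write a panel as a PLINK-1 bed/bim/fam triplet (SNP-major)."""
    prefix = Path(plink_prefix)
    n, p = panel.genotypes.shape
    snps = panel.snps
    bim = pd.DataFrame(
        {
            "chrom": snps.get("chrom", pd.Series(["1"] * p)),
            "snp_id": snps["snp_id"],
            "cm": 0,
            "pos": snps.get("pos", pd.Series(np.arange(1, p + 1))),
            "a1": snps["a1"],
            "a2": snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    # dosage -> 2-bit code; NaN -> 01
    g = panel.genotypes
    codes = np.full(g.shape, 1, dtype=np.uint8)  # missing
    codes[g == 2] = 0b00
    codes[g == 1] = 0b10
    codes[g == 0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.ones((bytes_per_snp * 4, p), dtype=np.uint8) * 0b11  # pad with hom-a2
    padded[:n] = codes
    packed = np.zeros((p, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[k::4].T.astype(np.uint8) << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        packed.tofile(fh)


# ---------------------------------------------------------------------------
# LD blocks


@dataclass
class LDBlockSet:
    """Ordered, non-overlapping genomic intervals (0-based half-open)."""

    blocks: pd.DataFrame  # columns: chrom (str), start, end

    def __post_init__(self) -> None:
        b = self.blocks
        if not {"chrom", "start", "end"} <= set(b.columns):
            raise FormatError("LD blocks need chrom/start/end columns")
        b = b.astype({"chrom": str, "start": np.int64, "end": np.int64})
        if (b["end"] <= b["start"]).any():
            raise FormatError("LD block with end <= start")
        b = b.sort_values(["chrom", "start"]).reset_index(drop=True)
        for _, grp in b.groupby("chrom"):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise FormatError(f"overlapping LD blocks on chromosome {grp['chrom'].iloc[0]}")
        self.blocks = b

    def __len__(self) -> int:
        return len(self.blocks)

    def assign(self, chrom: pd.Series, pos: pd.Series) -> np.ndarray:
        """Map SNPs (1-based bim positions) to block indices; -1 if outside.

        A SNP maps to a block iff ``start <= pos - 1 < end``.
        """
        out = np.full(len(chrom), -1, dtype=np.int64)
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # to 0-based
        chrom = np.asarray(chrom, dtype=str)
        for ch, grp in self.blocks.groupby("chrom"):
            mask = chrom == ch
            if not mask.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            idx = np.searchsorted(starts, pos0[mask], side="right") - 1
            ok = (idx >= 0) & (pos0[mask] < ends[np.clip(idx, 0, None)])
            res = np.where(ok, grp.index.to_numpy()[np.clip(idx, 0, None)], -1)
            out[mask] = res
        return out


def load_ld_blocks(path: str | Path) -> LDBlockSet:
    """Read a 3-column BED-like file of LD blocks (LDetect dialect)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if i == 0 and not parts[1].lstrip("-").isdigit():
                continue  # header line
            if len(parts) < 3:
                raise FormatError(f"{path}:{i + 1}: need 3 columns")
            rows.append((parts[0].removeprefix("chr"), int(parts[1]), int(parts[2])))
    if not rows:
        raise InputError(f"no intervals in {path}")
    return LDBlockSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def blocks_from_sizes(sizes: list[int], chrom: str = "1") -> LDBlockSet:
    """Blocks covering SNPs at positions 1..M split into consecutive runs."""
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return LDBlockSet(
        pd.DataFrame({"chrom": chrom, "start": edges[:-1], "end": edges[1:]})
    )


# ---------------------------------------------------------------------------
# Harmonization


@dataclass
class HarmonizedProblem:
    """Summary statistics aligned with a reference panel and LD blocks.

    ``df`` has one row per retained SNP with columns ``snp_id, chrom, pos,
    a1, a2, beta, se, n, pvalue, r, block, in_reference, panel_col, s_hat``.
    ``r`` is the SNP-phenotype correlation, ``s_hat`` the panel dosage SD
    (NaN for SNPs absent from the panel), ``panel_col`` the panel column
    index (-1 if absent). SNPs with ``in_reference == False`` form the
    mutually-independent group solved in closed form during fitting.
    """

    df: pd.DataFrame
    sd_y_hat: float
    n_eff: float
    log: dict = field(default_factory=dict)
    is_binary_trait: bool = False

    def __len__(self) -> int:
        return len(self.df)

    @property
    def r(self) -> np.ndarray:
        return self.df["r"].to_numpy()

    @property
    def in_reference(self) -> np.ndarray:
        return self.df["in_reference"].to_numpy()

    def block_groups(self) -> list[tuple[int, np.ndarray]]:
        """(block id, row positions) for SNPs present in the reference."""
        d = self.df.reset_index(drop=True)
        inref = d.index[d["in_reference"]]
        out = []
        for blk, grp in d.loc[inref].groupby("block", sort=True):
            out.append((int(blk), grp.index.to_numpy()))
        return out

    def to_sumstats(self) -> SummaryStats:
        cols = ["snp_id", "chrom", "pos", "a1", "a2", "beta", "se", "n", "pvalue"]
        return SummaryStats(
            self.df[[c for c in cols if c in self.df.columns]].reset_index(drop=True),
            is_binary_trait=self.is_binary_trait,
        )


def _r_from_t(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> np.ndarray:
    # exact for simple linear regression on standardized data:
    # t^2 = r^2 (n-2) / (1-r^2)  =>  r = t / sqrt(n - 2 + t^2)
    t = beta / se
    return t / np.sqrt(n - 2.0 + t**2)


def harmonize(
    ss: SummaryStats,
    panel: ReferencePanel,
    blocks: LDBlockSet | None = None,
    maf_min: float = 0.01,
    ld_clump_r2: float = 0.9,
    r_method: str = "t",
    sd_y: float | None = None,
    keep_missing: bool = True,
) -> HarmonizedProblem:
    """Align summary statistics with a reference panel into a fitting problem.

    Steps: intersect by snp_id (SNPs absent from the panel are retained with
    ``in_reference=False`` when ``keep_missing``), remove strand-ambiguous
    A/T and C/G SNPs, align alleles (flipping the sign of beta when effect
    and panel coding are swapped), filter on panel MAF, greedily clump within
    blocks so no retained pair exceeds ``ld_clump_r2`` (priority: ascending
    p-value, then position), and compute the SNP-phenotype correlation ``r``.

    ``r_method``: ``"t"`` (default) uses ``r = t / sqrt(n - 2 + t^2)``;
    ``"beta_sd"`` uses ``r = beta * s_hat / sd_y`` and requires ``sd_y``.
    """
    if not (0 < maf_min < 0.5):
        raise ConfigurationError("maf_min must lie in (0, 0.5)")
    if not (0 < ld_clump_r2 <= 1):
        raise ConfigurationError("ld_clump_r2 must lie in (0, 1]")

    d = ss.df.copy().reset_index(drop=True)
    log: dict[str, int] = {"input": len(d)}

    ambiguous = [(u, v) in AMBIGUOUS_PAIRS for u, v in zip(d["a1"], d["a2"])]
    log["dropped_ambiguous"] = int(np.sum(ambiguous))
    d = d.loc[~np.asarray(ambiguous)].reset_index(drop=True)

    pcol = {sid: j for j, sid in enumerate(panel.snps["snp_id"])}
    d["panel_col"] = [pcol.get(sid, -1) for sid in d["snp_id"]]
    matched = d["panel_col"] >= 0
    if not matched.any() and not keep_missing:
        raise InputError("no SNPs shared between summary statistics and panel")

    # allele orientation against the panel
    keep = np.ones(len(d), dtype=bool)
    flip = np.zeros(len(d), dtype=bool)
    pa1 = panel.snps["a1"].to_numpy()
    pa2 = panel.snps["a2"].to_numpy()
    for i in np.flatnonzero(matched.to_numpy()):
        j = d.at[i, "panel_col"]
        a1, a2 = d.at[i, "a1"], d.at[i, "a2"]
        if (a1, a2) == (pa1[j], pa2[j]):
            continue
        if (a1, a2) == (pa2[j], pa1[j]):
            flip[i] = True
        else:
            keep[i] = False
    log["dropped_allele_mismatch"] = int((~keep).sum())
    d.loc[flip, "beta"] = -d.loc[flip, "beta"]
    d.loc[flip, ["a1", "a2"]] = d.loc[flip, ["a2", "a1"]].to_numpy()
    d = d.loc[keep].reset_index(drop=True)
    matched = d["panel_col"] >= 0

    if not keep_missing:
        log["dropped_not_in_panel"] = int((~matched).sum())
        d = d.loc[matched].reset_index(drop=True)
        matched = d["panel_col"] >= 0
    if len(d) == 0 or (keep_missing and not len(d)):
        raise InputError("zero SNPs retained after allele harmonization")

    # panel-derived quantities
    cols = d.loc[matched, "panel_col"].to_numpy()
    maf = panel.maf()
    sds = panel.sd()
    low_maf = np.zeros(len(d), dtype=bool)
    low_maf[np.flatnonzero(matched.to_numpy())] = (maf[cols] < maf_min) | (sds[cols] <= 0)
    log["dropped_maf"] = int(low_maf.sum())
    d = d.loc[~low_maf].reset_index(drop=True)
    if len(d) == 0:
        raise InputError("zero SNPs retained after MAF filtering")
    matched = (d["panel_col"] >= 0).to_numpy()

    # fill chrom/pos from the panel where absent in the sumstats
    for key in ("chrom", "pos"):
        if key not in d.columns:
            d[key] = pd.Series([None] * len(d), dtype=object)
        fill = d[key].isna() & matched
        if fill.any():
            d[key] = d[key].astype(object)
            d.loc[fill, key] = panel.snps[key].to_numpy()[d.loc[fill, "panel_col"]]

    # block assignment; SNPs outside all intervals (or not in the panel)
    # become singleton pseudo-blocks
    block = np.full(len(d), -1, dtype=np.int64)
    if blocks is not None:
        ok = matched & d["pos"].notna().to_numpy()
        block[ok] = blocks.assign(d.loc[ok, "chrom"].astype(str), d.loc[ok, "pos"])
    next_id = int(block.max()) + 1 if (block >= 0).any() else 0
    singles = np.flatnonzero(block < 0)
    block[singles] = np.arange(next_id, next_id + len(singles))
    d["block"] = block

    # greedy LD clumping within blocks (priority: p-value, then position)
    if "pvalue" not in d.columns:
        z = d["beta"] / d["se"]
        d["pvalue"] = 2.0 * _stats.norm.sf(np.abs(z))
    X = panel.imputed()
    drop_clump = np.zeros(len(d), dtype=bool)
    for _, grp in d.loc[matched].groupby("block"):
        if len(grp) < 2:
            continue
        order = grp.sort_values(["pvalue", "pos"], kind="mergesort").index.to_numpy()
        g = X[:, d.loc[order, "panel_col"].to_numpy()]
        g = (g - g.mean(axis=0)) / g.std(axis=0)
        corr2 = (g.T @ g / g.shape[0]) ** 2
        kept: list[int] = []
        for i in range(len(order)):
            if any(corr2[i, j] > ld_clump_r2 for j in kept):
                drop_clump[order[i]] = True
            else:
                kept.append(i)
    log["dropped_clump"] = int(drop_clump.sum())
    d = d.loc[~drop_clump].reset_index(drop=True)
    matched = (d["panel_col"] >= 0).to_numpy()

    d["in_reference"] = matched
    s_hat = np.full(len(d), np.nan)
    s_hat[matched] = sds[d.loc[matched, "panel_col"].to_numpy()]
    d["s_hat"] = s_hat

    # phenotype SD from the moment identity (1/N) Y'Y ~ N s^2 var(beta) + s^2 beta^2
    with np.errstate(invalid="ignore"):
        var_y_terms = d["n"] * d["se"] ** 2 * s_hat**2 + s_hat**2 * d["beta"] ** 2
    sd_y_hat = float(np.sqrt(np.nanmedian(var_y_terms))) if matched.any() else np.nan

    if r_method == "t":
        r = _r_from_t(d["beta"].to_numpy(), d["se"].to_numpy(), d["n"].to_numpy())
    elif r_method == "beta_sd":
        use_sd = sd_y if sd_y is not None else sd_y_hat
        if use_sd is None or not np.isfinite(use_sd):
            raise ConfigurationError("r_method='beta_sd' needs a phenotype SD")
        r = d["beta"].to_numpy() * np.nan_to_num(s_hat, nan=1.0) / use_sd
    else:
        raise ConfigurationError(f"unknown r_method {r_method!r}")
    d["r"] = np.clip(r, -1.0, 1.0)

    log["retained"] = len(d)
    logger.info("harmonization: %s", log)
    return HarmonizedProblem(
        d,
        sd_y_hat=sd_y_hat,
        n_eff=float(np.median(d["n"])),
        log=log,
        is_binary_trait=ss.is_binary_trait,
    )
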