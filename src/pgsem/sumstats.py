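"""GWAS summary-statistic tables: reading, QC, harmonization, meta-analysis.

The canonical on-disk dialect is whitespace/tab-delimited text with header
``SNP CHR BP A1 A2 BETA SE P N MAF [INFO]``.  ``A1`` is always the effect
(counted) allele; ``BETA`` is the per-allele regression coefficient
(log odds ratio for binary traits); positions are 1-based.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N", "MAF"]
OPTIONAL_COLUMNS = ["INFO"]

#: header synonyms accepted by :func:`read_sumstats` (lower-cased lookup)
COLUMN_SYNONYMS = {
    "SNP": ["snp", "rsid", "rs_id", "markername", "marker", "id", "snpid", "variant_id"],
    "CHR": ["chr", "chrom", "chromosome", "#chrom"],
    "BP": ["bp", "pos", "position", "base_pair_location"],
    "A1": ["a1", "effect_allele", "allele1", "ea", "alt"],
    "A2": ["a2", "other_allele", "allele2", "oa", "ref", "a0"],
    "BETA": ["beta", "b", "effect", "est", "effect_size"],
    "OR": ["or", "odds_ratio", "oddsratio"],
    "SE": ["se", "stderr", "standard_error", "se_beta"],
    "P": ["p", "pval", "p_value", "pvalue", "p.value"],
    "N": ["n", "nobs", "sample_size", "neff", "n_total"],
    "MAF": ["maf", "freq", "frq", "eaf", "af", "effect_allele_frequency"],
    "INFO": ["info", "imputation_quality", "rsq"],
}

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SumStatsError(ValueError):
    pass


@dataclass
class SumStats:
    """Per-SNP association table for a single trait.

    ``table`` holds the canonical columns of :data:`REQUIRED_COLUMNS` (plus
    optional ``INFO``); ``trait`` is a free-form label used downstream.
    """

    table: pd.DataFrame
    trait: str = "trait"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise SumStatsError(f"missing mandatory column(s): {', '.join(missing)}")
        self.table = self.table.reset_index(drop=True)

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def z(self) -> np.ndarray:
        """Z-score ``beta / se`` (NaN where se is not positive)."""
        se = self.table["SE"].to_numpy(float)
        beta = self.table["BETA"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta / se, np.nan)
        return z

    def validate(self, z_p_rtol: float = 1e-3) -> None:
        """Check container invariants; raise :class:`SumStatsError` on violation."""
        t = self.table
        if t["SNP"].duplicated().any():
            raise SumStatsError("duplicate SNP ids")
        for col in ("A1", "A2"):
            bad = ~t[col].astype(str).isin(_VALID_ALLELES)
            if bad.any():
                raise SumStatsError(f"non-ACGT alleles in {col}")
        p = t["P"].to_numpy(float)
        if np.any((p <= 0) | (p > 1)):
            raise SumStatsError("p-values outside (0, 1]")
        z = self.z
        ok = np.isfinite(z) & (p > 1e-300)  # skip truncated / NA rows
        implied = 2.0 * stats.norm.sf(np.abs(z[ok]))
        rel = np.abs(implied - p[ok]) / np.maximum(p[ok], 1e-300)
        if np.any((rel > z_p_rtol) & (implied > 1e-300)):
            raise SumStatsError("|z| inconsistent with stored p beyond tolerance")

    def recompute_p(self) -> int:
        """Replace stored p with the two-sided normal p implied by z where they
        disagree by more than 1e-3 relative; returns the number of rows changed."""
        z = self.z
        implied = 2.0 * stats.norm.sf(np.abs(z))
        p = self.table["P"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(implied - p) / np.maximum(p, 1e-300)
        fix = np.isfinite(z) & (rel > 1e-3)
        if fix.any():
            logger.info("%s: recomputed %d p-values from z", self.trait, int(fix.sum()))
            self.table.loc[fix, "P"] = np.clip(implied[fix], 1e-300, 1.0)
        return int(fix.sum())

    # ------------------------------------------------------------------
    def write(self, path) -> None:
        """Write the canonical tab-delimited dialect (gzip if path ends .gz)."""
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            self.table.to_csv(fh, sep="\t", index=False, na_rep="NA")

    def copy(self) -> "SumStats":
        return SumStats(self.table.copy(), trait=self.trait, meta=dict(self.meta))


@dataclass
class HarmonizedSet:
    """SumStats tables restricted to a common SNP universe with identical
    SNP order and effect-allele orientation."""

    members: list
    n_flipped: int = 0
    n_dropped: int = 0

    def __post_init__(self):
        if len(self.members) < 2:
            raise SumStatsError("harmonized set requires >= 2 tables")

    def __len__(self) -> int:
        return len(self.members[0])

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def traits(self) -> list:
        return [m.trait for m in self.members]

    @property
    def snps(self) -> pd.Series:
        return self.members[0].table["SNP"]

    def betas(self) -> np.ndarray:
        return np.column_stack([m.table["BETA"].to_numpy(float) for m in self.members])

    def ses(self) -> np.ndarray:
        return np.column_stack([m.table["SE"].to_numpy(float) for m in self.members])

    def zscores(self) -> np.ndarray:
        return np.column_stack([m.z for m in self.members])

    def nobs(self) -> np.ndarray:
        return np.column_stack([m.table["N"].to_numpy(float) for m in self.members])


# ----------------------------------------------------------------------
def _resolve_columns(columns, column_map=None) -> dict:
    """Map canonical names to actual header names; user map wins."""
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canon, synonyms in COLUMN_SYNONYMS.items():
        if column_map and canon in column_map:
            resolved[canon] = column_map[canon]
            continue
        for s in synonyms:
            if s in lower:
                resolved[canon] = lower[s]
                break
    return resolved


def read_sumstats(path, column_map: dict | None = None, trait: str | None = None) -> SumStats:
    """Read a summary-statistic table, accepting flexible header synonyms.

    Odds-ratio columns are converted to ``BETA = ln(OR)``.  Rows failing
    numeric coercion are dropped (count logged).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    if df.empty:
        raise SumStatsError(f"{path}: no records")
    resolved = _resolve_columns(df.columns, column_map)
    use_or = "BETA" not in resolved and "OR" in resolved
    needed = [c for c in REQUIRED_COLUMNS if c != "BETA"] + (["OR"] if use_or else ["BETA"])
    missing = [c for c in needed if c not in resolved]
    if missing:
        raise SumStatsError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    out = pd.DataFrame()
    out["SNP"] = df[resolved["SNP"]].astype(str)
    out["CHR"] = pd.to_numeric(df[resolved["CHR"]].str.replace("chr", "", regex=False),
                               errors="coerce")
    out["BP"] = pd.to_numeric(df[resolved["BP"]], errors="coerce")
    out["A1"] = df[resolved["A1"]].str.upper()
    out["A2"] = df[resolved["A2"]].str.upper()
    if use_or:
        orv = pd.to_numeric(df[resolved["OR"]], errors="coerce")
        out["BETA"] = np.log(orv.where(orv > 0))
    else:
        out["BETA"] = pd.to_numeric(df[resolved["BETA"]], errors="coerce")
    for canon in ("SE", "P", "N", "MAF"):
        out[canon] = pd.to_numeric(df[resolved[canon]], errors="coerce")
    if "INFO" in resolved:
        out["INFO"] = pd.to_numeric(df[resolved["INFO"]], errors="coerce")

    before = len(out)
    numeric = ["CHR", "BP", "BETA", "SE", "P", "N", "MAF"]
    out = out.dropna(subset=numeric)
    dropped = before - len(out)
    if dropped:
        logger.info("%s: dropped %d rows failing type coercion", path, dropped)
    if out.empty:
        raise SumStatsError(f"{path}: no records after type coercion")
    out["CHR"] = out["CHR"].astype(int)
    out["BP"] = out["BP"].astype(int)
    return SumStats(out, trait=trait or str(path))


def munge(ss: SumStats, maf_min: float = 0.01, info_min: float = 0.9,
          drop_ambiguous: bool = True) -> SumStats:
    """LDSC-style QC: drop low-MAF, low-INFO, non-positive-SE, strand-ambiguous
    (A/T, C/G) and duplicate-id SNPs.  All drops are logged by reason."""
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= info_min <= 1:
        raise ValueError("info_min must be in [0, 1]")
    t = ss.table
    reasons = {}
    keep = np.ones(len(t), dtype=bool)

    bad_allele = ~(t["A1"].isin(_VALID_ALLELES) & t["A2"].isin(_VALID_ALLELES))
    reasons["invalid_alleles"] = int((bad_allele & keep).sum())
    keep &= ~bad_allele

    bad_se = ~(t["SE"].to_numpy(float) > 0)
    reasons["nonpositive_se"] = int((bad_se & keep).sum())
    keep &= ~bad_se

    maf = t["MAF"].to_numpy(float)
    maf = np.minimum(maf, 1 - maf)
    bad_maf = ~(maf >= maf_min)
    reasons["low_maf"] = int((bad_maf & keep).sum())
    keep &= ~bad_maf

    if "INFO" in t.columns:
        bad_info = t["INFO"].to_numpy(float) < info_min
        reasons["low_info"] = int((bad_info & keep).sum())
        keep &= ~bad_info

    if drop_ambiguous:
        amb = pd.Series(list(zip(t["A1"], t["A2"]))).isin(_AMBIGUOUS_PAIRS).to_numpy()
        reasons["strand_ambiguous"] = int((amb & keep).sum())
        keep &= ~amb

    dup = t["SNP"].duplicated(keep="first").to_numpy()
    reasons["duplicate_id"] = int((dup & keep).sum())
    keep &= ~dup

    for reason, n in reasons.items():
        if n:
            logger.info("munge[%s]: dropped %d SNPs (%s)", ss.trait, n, reason)
    out = SumStats(t.loc[keep].reset_index(drop=True), trait=ss.trait,
                   meta={**ss.meta, "munge_drops": reasons})
    # stored p loses to the p implied by beta/se when they disagree
    out.meta["n_p_recomputed"] = out.recompute_p()
    return out


def harmonize(tables: list) -> HarmonizedSet:
    """Intersect tables on SNP id and align every member to the first table's
    A1/A2 orientation, negating beta (and reflecting MAF) for swapped rows;
    SNPs with incompatible alleles are dropped everywhere."""
    if len(tables) < 2:
        raise SumStatsError("harmonize requires >= 2 tables")
    common = tables[0].table["SNP"].drop_duplicates()
    for t in tables[1:]:
        common = common[common.isin(set(t.table["SNP"]))]
    if common.empty:
        raise SumStatsError("empty SNP intersection")
    common = common.reset_index(drop=True)
    for t in tables:
        if t.table["SNP"].duplicated().any():
            raise SumStatsError(f"{t.trait}: duplicate SNP ids (munge first)")

    ref = tables[0].table.set_index("SNP").loc[common]
    members, n_flipped = [], 0
    drop = np.zeros(len(common), dtype=bool)
    aligned_tables = []
    for t in tables:
        tt = t.table.set_index("SNP").loc[common].copy()
        same = (tt["A1"] == ref["A1"]) & (tt["A2"] == ref["A2"])
        swapped = (tt["A1"] == ref["A2"]) & (tt["A2"] == ref["A1"])
        incompatible = ~(same | swapped)
        drop |= incompatible.to_numpy()
        n_flipped += int(swapped.sum())
        tt.loc[swapped, "BETA"] = -tt.loc[swapped, "BETA"]
        tt.loc[swapped, "MAF"] = 1.0 - tt.loc[swapped, "MAF"]
        tt.loc[swapped, ["A1", "A2"]] = ref.loc[swapped.to_numpy(), ["A1", "A2"]].to_numpy()
        aligned_tables.append(tt)
    for t, tt in zip(tables, aligned_tables):
        kept = tt.loc[~drop].reset_index()
        members.append(SumStats(kept, trait=t.trait, meta=dict(t.meta)))
    if drop.any():
        logger.info("harmonize: dropped %d SNPs with incompatible alleles", int(drop.sum()))
    return HarmonizedSet(members, n_flipped=n_flipped, n_dropped=int(drop.sum()))


def meta_analyze(ss1: SumStats, ss2: SumStats, overlap_correlation: float = 0.0,
                 overlap_fraction: float | None = None,
                 trait: str | None = None) -> SumStats:
    """Dependent inverse-variance-weighted fixed-effect meta-analysis.

    The combined variance is inflated for between-study dependence::

        var = w1^2 v1 + w2^2 v2 + 2 w1 w2 rho sqrt(v1 v2)

    with ``w`` the IVW weights and ``rho = overlap_correlation`` (e.g. the
    cross-trait LDSC intercept between the two studies).  ``N`` is summed;
    when ``overlap_fraction`` is given the shared portion is counted once.
    """
    if not 0 <= overlap_correlation < 1:
        raise ValueError("overlap_correlation must be in [0, 1)")
    h = harmonize([ss1, ss2])
    a, b = h.members
    v1 = a.table["SE"].to_numpy(float) ** 2
    v2 = b.table["SE"].to_numpy(float) ** 2
    w1 = (1 / v1) / (1 / v1 + 1 / v2)
    w2 = 1.0 - w1
    beta = w1 * a.table["BETA"].to_numpy(float) + w2 * b.table["BETA"].to_numpy(float)
    var = w1 ** 2 * v1 + w2 ** 2 * v2 + 2 * w1 * w2 * overlap_correlation * np.sqrt(v1 * v2)
    se = np.sqrt(var)
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    n1 = a.table["N"].to_numpy(float)
    n2 = b.table["N"].to_numpy(float)
    n = n1 + n2
    if overlap_fraction is not None:
        n = n - overlap_fraction * np.minimum(n1, n2)
    out = a.table.copy()
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = p
    out["N"] = n
    out["MAF"] = (w1 * a.table["MAF"].to_numpy(float) + w2 * b.table["MAF"].to_numpy(float))
    return SumStats(out, trait=trait or f"meta({a.trait},{b.trait})",
                    meta={"overlap_correlation": overlap_correlation})
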