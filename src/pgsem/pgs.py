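"""Polygenic scores by LD clumping and p-value thresholding, with the
threshold selected by summary-statistic subsampling cross-validation.

The tuning stage needs no individual-level data: on the standardized
(correlation) scale ``r_j = z_j / sqrt(N_j)``, a training replicate is drawn
as ``r_tr ~ Normal(r_hat, 1/N_tr - 1/N)`` and the complementary test
statistic ``r_te = (N r_hat - N_tr r_tr) / N_te`` satisfies
``N_tr r_tr + N_te r_te = N r_hat`` exactly.  Predictive r^2 of a weight
vector ``w`` over the clumped (approximately independent) SNP set is
``(sum_j w_j r_te,j)^2 / sum_j w_j^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumStats

logger = logging.getLogger(__name__)

__all__ = [
    "PGSWeights", "ThresholdCV", "clump", "subsample_sumstats",
    "cv_select_threshold", "compute_pgs", "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (1.0, 0.1, 0.01, 0.001, 0.0001, 5e-8)


@dataclass
class PGSWeights:
    """Post-clumping, post-threshold per-SNP weights keyed to the effect allele."""

    table: pd.DataFrame          # SNP, A1, weight, p_source, CHR, BP
    threshold: float
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        self.table[["SNP", "A1", "weight", "p_source"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_sumstats(cls, ss: SumStats, threshold: float = 1.0,
                      provenance: dict | None = None) -> "PGSWeights":
        t = ss.table
        keep = t["P"].to_numpy(float) <= threshold
        table = pd.DataFrame({
            "SNP": t.loc[keep, "SNP"], "A1": t.loc[keep, "A1"],
            "weight": t.loc[keep, "BETA"].to_numpy(float),
            "p_source": t.loc[keep, "P"].to_numpy(float),
            "CHR": t.loc[keep, "CHR"], "BP": t.loc[keep, "BP"],
        }).reset_index(drop=True)
        return cls(table=table, threshold=threshold, provenance=provenance or
                   {"source": ss.trait})


# ======================================================================
def _r2_lookup(ld):
    """Return a function r2(i, j) over positional SNP indices for either an
    LD panel (true R) or a reference dosage matrix."""
    from .simulate import LDPanel

    if isinstance(ld, LDPanel):
        R = ld.R
        return lambda i, jarr: R[i, jarr] ** 2
    G = np.asarray(ld, float)
    sd = G.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Gs = (G - G.mean(axis=0)) / sd
    n = G.shape[0]

    def r2(i, jarr):
        return (Gs[:, jarr].T @ Gs[:, i] / n) ** 2
    return r2


def clump(ss: SumStats, ld, window_kb: float = 1000.0, r2_max: float = 0.1,
          p_max: float = 1.0) -> SumStats:
    """Greedy LD clumping: repeatedly take the smallest-p unclaimed SNP as an
    index SNP and claim all unclaimed SNPs within ``window_kb`` whose r^2
    with it exceeds ``r2_max``.  Index SNPs are returned in selection order.

    Ties on p are broken by (chrom, position) ascending so output is
    invariant to input row order.  ``ld`` is an :class:`~pgsem.simulate.LDPanel`
    or a reference dosage matrix whose columns follow the panel SNP order
    (SNPs absent from the reference are dropped with a log message).
    """
    t = ss.table
    from .simulate import LDPanel

    if isinstance(ld, LDPanel):
        ref_ids = pd.Index(ld.snp_ids)
    else:
        ref_ids = None
    if ref_ids is not None:
        in_ref = t["SNP"].isin(ref_ids)
        if not in_ref.all():
            logger.info("clump: dropped %d SNPs absent from the LD reference",
                        int((~in_ref).sum()))
        t = t[in_ref]
        ld_pos = ref_ids.get_indexer(t["SNP"])
    else:
        ld_pos = np.arange(len(t))

    t = t.reset_index(drop=True)
    finite_p = np.isfinite(t["P"].to_numpy(float))
    t = t[finite_p].reset_index(drop=True)
    ld_pos = ld_pos[finite_p]
    order = np.lexsort((t["BP"].to_numpy(), t["CHR"].to_numpy(),
                        t["P"].to_numpy(float)))
    r2 = _r2_lookup(ld)
    pos = t["BP"].to_numpy(float)
    chrom = t["CHR"].to_numpy()
    claimed = np.zeros(len(t), dtype=bool)
    window_bp = window_kb * 1000.0
    picked = []
    pvals = t["P"].to_numpy(float)
    for i in order:
        if claimed[i] or pvals[i] > p_max:
            continue
        picked.append(i)
        claimed[i] = True
        near = np.flatnonzero((chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
                              & ~claimed)
        if len(near):
            rr = r2(ld_pos[i], ld_pos[near])
            claimed[near[rr > r2_max]] = True
    out = t.iloc[picked].reset_index(drop=True)
    return SumStats(out, trait=ss.trait,
                    meta={**ss.meta, "clump_window_kb": window_kb, "clump_r2": r2_max})


# ======================================================================
def subsample_sumstats(ss: SumStats, train_fraction: float = 0.75,
                       seed: int = 0) -> tuple[SumStats, SumStats]:
    """Split one GWAS into pseudo-independent training/test replicates on the
    standardized scale (no individual-level data needed)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    t = ss.table
    N = t["N"].to_numpy(float)
    if np.any(~np.isfinite(N)) or np.any(N <= 0):
        bad = t.loc[~np.isfinite(N) | (N <= 0), "SNP"].tolist()[:5]
        raise ValueError(f"missing/invalid N for SNPs, e.g. {bad}")
    z = ss.z
    r_hat = z / np.sqrt(N)
    n_tr = train_fraction * N
    n_te = N - n_tr
    rng = np.random.default_rng(seed)
    sd = np.sqrt(np.maximum(1.0 / n_tr - 1.0 / N, 0.0))
    r_tr = r_hat + rng.standard_normal(len(r_hat)) * sd
    r_te = (N * r_hat - n_tr * r_tr) / n_te

    def _as_ss(r, n, tag):
        se = 1.0 / np.sqrt(n)
        zz = r / se
        out = t.copy()
        out["BETA"] = r
        out["SE"] = se
        out["P"] = np.clip(2.0 * stats.norm.sf(np.abs(zz)), 1e-300, 1.0)
        out["N"] = n
        return SumStats(out, trait=f"{ss.trait}[{tag}]",
                        meta={**ss.meta, "subsample": tag})

    return _as_ss(r_tr, n_tr, "train"), _as_ss(r_te, n_te, "test")


@dataclass
class ThresholdCV:
    """Cross-validated threshold selection record."""

    thresholds: tuple
    fold_r2: np.ndarray          # (folds, n_thresholds)
    mean_r2: np.ndarray
    selected: float
    folds: int
    train_fraction: float

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fold_r2,
                          columns=[f"{t:g}" for t in self.thresholds])
        df.loc["mean"] = self.mean_r2
        return df


def cv_select_threshold(ss: SumStats, thresholds=DEFAULT_THRESHOLDS, folds: int = 4,
                        train_fraction: float = 0.75, seed: int = 0) -> ThresholdCV:
    """Pick the p-value threshold maximizing mean out-of-sample r^2 across
    subsampling folds (clumped input assumed; SNPs treated as independent)."""
    thresholds = tuple(float(x) for x in thresholds)
    fold_r2 = np.zeros((folds, len(thresholds)))
    for f in range(folds):
        tr, te = subsample_sumstats(ss, train_fraction, seed=seed + f)
        r_tr = tr.table["BETA"].to_numpy(float)
        p_tr = tr.table["P"].to_numpy(float)
        r_te = te.table["BETA"].to_numpy(float)
        for c, thr in enumerate(thresholds):
            sel = p_tr <= thr
            if not sel.any():
                fold_r2[f, c] = 0.0
                continue
            w = r_tr[sel]
            denom = float(np.sum(w ** 2))
            fold_r2[f, c] = float(np.sum(w * r_te[sel])) ** 2 / denom if denom > 0 else 0.0
    mean_r2 = fold_r2.mean(axis=0)
    selected = thresholds[int(np.argmax(mean_r2))]
    return ThresholdCV(thresholds=thresholds, fold_r2=fold_r2, mean_r2=mean_r2,
                       selected=selected, folds=folds, train_fraction=train_fraction)


# ======================================================================
def compute_pgs(weights: PGSWeights, genotypes: np.ndarray, snp_ids, effect_alleles,
                other_alleles=None, standardize: bool = True,
                sample_ids=None) -> pd.DataFrame:
    """Score individuals: ``score_i = sum_j w_j dosage_ij`` after allele
    alignment.

    ``genotypes`` columns follow ``snp_ids``/``effect_alleles`` (the allele the
    dosage counts).  Weights whose effect allele is the column's *other*
    allele are applied to the flipped dosage ``2 - d``; weights for SNPs
    missing from the genotypes are dropped with a count; missing (NaN)
    dosages are mean-imputed per SNP.  Scores are z-standardized
    unless the variance is zero, in which case the unstandardized scores are
    returned with a warning.
    """
    snp_ids = pd.Index(np.asarray(snp_ids, dtype=str))
    wtab = weights.table
    locs = snp_ids.get_indexer(wtab["SNP"])
    found = locs >= 0
    n_missing = int((~found).sum())
    if n_missing:
        logger.info("compute_pgs: %d weight SNPs missing from genotypes", n_missing)
        if n_missing > 0.2 * len(wtab):
            logger.warning("compute_pgs: >20%% of weight SNPs missing")
    wtab = wtab[found]
    locs = locs[found]
    eff = np.asarray(effect_alleles, dtype=str)[locs]
    w_alleles = wtab["A1"].to_numpy(dtype=str)
    match = w_alleles == eff
    if other_alleles is not None:
        oth = np.asarray(other_alleles, dtype=str)[locs]
        flip = w_alleles == oth
    else:
        flip = ~match
    usable = match | flip
    if not usable.all():
        logger.info("compute_pgs: dropped %d weight SNPs with unalignable alleles",
                    int((~usable).sum()))
    wtab, locs = wtab[usable], locs[usable]
    match, flip = match[usable], flip[usable]

    w = wtab["weight"].to_numpy(float)
    D = genotypes[:, locs].astype(float)
    if np.isnan(D).any():
        col_mean = np.nanmean(D, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(D))
        D[nan_r, nan_c] = col_mean[nan_c]
    D[:, flip] = 2.0 - D[:, flip]
    scores = D @ w
    sd = scores.std()
    if standardize:
        if sd == 0:
            logger.warning("compute_pgs: zero score variance; returning unstandardized")
        else:
            scores = (scores - scores.mean()) / sd
    if sample_ids is None:
        sample_ids = [f"id{i + 1}" for i in range(len(scores))]
    return pd.DataFrame({"sample_id": sample_ids, "score": scores})
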