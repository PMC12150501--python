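"""Synthetic multi-trait GWAS study generator.

Every downstream stage of the pipeline (LD score regression, genomic SEM,
clumping/thresholding scores, association tests) is verifiable against the
generating values produced here.  The generator emulates:

* block-wise LD among SNPs (AR(1) within block, independence across blocks)
  on a single pseudo-chromosome with configurable inter-SNP spacing;
* hard-call genotypes built from two independent haplotypes, each a binary
  Markov chain over the block's SNPs.  For a stationary two-state chain the
  lag-k correlation is the product of adjacent correlations, so genotype LD
  is *exactly* the panel's AR(1) matrix, allele frequencies are exact, and
  Hardy-Weinberg holds by construction -- no external reference needed.
  (Frechet bounds on binary correlations require similar frequencies within
  a block, so MAF is drawn per block, constant within it.);
* k genetically correlated traits whose genetic covariance follows a
  low-rank factor structure plus trait-specific residuals, with liability
  thresholding for case-control traits;
* GWAS cohorts with controllable pairwise sample overlap (overlapping
  individuals share genotypes and environmental draws);
* target samples (population or all-cases ascertained) with symptom-count
  and binary outcomes plus sex/age/PC covariate columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import stage_rng
from .sumstats import SumStats

logger = logging.getLogger(__name__)

__all__ = [
    "LDPanel", "TrueArchitecture", "CohortSpec", "GroundTruth", "GwasSuite",
    "simulate_ld_panel", "simulate_genotypes", "simulate_multitrait_phenotypes",
    "run_gwas", "make_gwas_suite", "simulate_target_cohort", "PhenotypeSet",
]


# ======================================================================
# LD panel
# ======================================================================
@dataclass(frozen=True)
class LDPanel:
    """Block-diagonal AR(1) LD structure for ``m`` SNPs on one pseudo-chromosome.

    ``R[i, j] = rho_b ** |i - j|`` within block ``b`` and 0 across blocks.
    Positions are 1-based and strictly increasing.
    """

    block_sizes: tuple
    block_rhos: tuple
    maf: np.ndarray
    positions: np.ndarray
    chrom: int = 1

    @property
    def m(self) -> int:
        return len(self.maf)

    @property
    def block_slices(self) -> list:
        out, start = [], 0
        for s in self.block_sizes:
            out.append(slice(start, start + s))
            start += s
        return out

    @property
    def R(self) -> np.ndarray:
        """Dense true LD correlation matrix (built on demand)."""
        if self.m > 20000:
            raise MemoryError("dense R refused for m > 20000")
        R = np.zeros((self.m, self.m))
        for sl, rho in zip(self.block_slices, self.block_rhos):
            idx = np.arange(sl.stop - sl.start)
            R[sl, sl] = rho ** np.abs(idx[:, None] - idx[None, :])
        return R

    @property
    def snp_ids(self) -> np.ndarray:
        return np.array([f"rs{i + 1}" for i in range(self.m)])


def simulate_ld_panel(block_sizes, rhos, maf_range=(0.05, 0.5), m: int | None = None,
                      spacing_bp: int = 5000, seed: int = 0) -> LDPanel:
    """Build an :class:`LDPanel` with AR(1) blocks and uniform MAF draws.

    ``rhos`` may be a scalar (shared by all blocks) or one value per block,
    each in ``[0, 1)``.  ``spacing_bp`` sets the constant inter-SNP distance
    (default 5 kb, so a 1000 kb clumping window spans 200 SNPs).
    """
    block_sizes = tuple(int(s) for s in block_sizes)
    if np.isscalar(rhos):
        rhos = (float(rhos),) * len(block_sizes)
    rhos = tuple(float(r) for r in rhos)
    if len(rhos) != len(block_sizes):
        raise ValueError("one rho per block required")
    if any(not 0 <= r < 1 for r in rhos):
        raise ValueError("rho must be in [0, 1)")
    if any(s < 1 for s in block_sizes):
        raise ValueError("block sizes must be >= 1")
    total = sum(block_sizes)
    if m is not None and m != total:
        raise ValueError(f"m={m} does not equal sum of block sizes ({total})")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = stage_rng(seed, "panel")
    # one MAF per block (constant within): binary variables with disparate
    # frequencies cannot attain high correlations (Frechet bounds)
    block_maf = rng.uniform(lo, hi, size=len(block_sizes))
    maf = np.repeat(block_maf, block_sizes)
    positions = (1 + spacing_bp * np.arange(total)).astype(np.int64)
    return LDPanel(block_sizes=block_sizes, block_rhos=rhos, maf=maf, positions=positions)


def simulate_genotypes(panel: LDPanel, n: int, seed: int = 0) -> np.ndarray:
    """Draw an ``(n, m)`` dosage matrix with values in {0, 1, 2}.

    Two independent haplotypes per individual; within a block each haplotype
    is a stationary binary Markov chain with marginal frequency ``maf`` and
    adjacent correlation ``rho``.  Lag-k correlations of a two-state chain
    telescope (``corr(X_i, X_{i+k}) = rho^k``), so the genotype correlation
    matrix equals the panel's ``R`` exactly and HWE holds by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = stage_rng(seed, "genotypes")
    # F-order: downstream stages work on contiguous column blocks
    G = np.empty((n, panel.m), dtype=np.int8, order="F")
    for sl, rho in zip(panel.block_slices, panel.block_rhos):
        s = sl.stop - sl.start
        f = float(panel.maf[sl.start])
        u = rng.random((s, 2 * n), dtype=np.float32)
        x = np.empty((s, 2 * n), dtype=np.int8)
        x[0] = u[0] < f
        # P(1 | prev=1) = f + rho (1 - f);  P(1 | prev=0) = f (1 - rho)
        p_stay, p_gain = f + rho * (1.0 - f), f * (1.0 - rho)
        for j in range(1, s):
            thresh = np.where(x[j - 1] == 1, np.float32(p_stay), np.float32(p_gain))
            x[j] = u[j] < thresh
        x = x.T
        G[:, sl] = x[:n] + x[n:]
    return G


def expected_genotype_correlation(panel: LDPanel, i: int, j: int) -> float:
    """Closed-form expected dosage correlation between SNPs i and j (the
    panel ``R`` entry): ``rho^|i-j|`` within a block, 0 across blocks."""
    for sl, rho in zip(panel.block_slices, panel.block_rhos):
        if sl.start <= i < sl.stop:
            if sl.start <= j < sl.stop:
                return float(rho ** abs(i - j))
            return 0.0
    raise IndexError(i)


# ======================================================================
# Trait architecture
# ======================================================================
@dataclass
class TrueArchitecture:
    """Generating genetic architecture for ``k`` traits and ``q`` factors.

    On the standardized genetic scale ``diag(Lambda Phi Lambda') + Psi = 1``;
    trait t's genetic value is ``sqrt(h2_t) * (Lambda_t . F + s_t)`` with unit
    total variance before the h2 scaling.  ``prevalence[t]`` switches trait t
    to case-control via liability thresholding.
    """

    Lambda: np.ndarray                       # (k, q)
    Psi: np.ndarray                          # (k,)
    h2: np.ndarray                           # (k,)
    Phi: np.ndarray | None = None            # (q, q) factor correlations
    factor_causal_fraction: float = 1.0
    specific_causal_fraction: float = 1.0
    factor_causal_mask: np.ndarray | None = None    # (m, q) bool, overrides fraction
    specific_causal_mask: np.ndarray | None = None  # (m, k) bool, overrides fraction
    prevalence: np.ndarray | None = None     # (k,) or None; NaN => quantitative
    trait_labels: list | None = None

    def __post_init__(self):
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, float))
        self.Psi = np.asarray(self.Psi, float)
        self.h2 = np.asarray(self.h2, float)
        if self.Phi is None:
            self.Phi = np.eye(self.q)
        self.Phi = np.asarray(self.Phi, float)
        if np.any((self.h2 < 0) | (self.h2 > 1)):
            raise ValueError("h2 must be in [0, 1]")
        common = np.diag(self.Lambda @ self.Phi @ self.Lambda.T)
        if not np.allclose(common + self.Psi, 1.0, atol=1e-6):
            raise ValueError("diag(Lambda Phi Lambda') + Psi must equal 1")
        if np.linalg.eigvalsh(self.genetic_correlation()).min() < -1e-8:
            raise ValueError("implied genetic correlation matrix is not PSD")
        if self.trait_labels is None:
            self.trait_labels = [f"trait{i}" for i in range(self.k)]

    @property
    def k(self) -> int:
        return self.Lambda.shape[0]

    @property
    def q(self) -> int:
        return self.Lambda.shape[1]

    def genetic_correlation(self) -> np.ndarray:
        C = self.Lambda @ self.Phi @ self.Lambda.T + np.diag(self.Psi)
        return (C + C.T) / 2

    def genetic_covariance(self) -> np.ndarray:
        """True S on the standardized (observed for binary) phenotype scale."""
        d = np.sqrt(self.h2)
        return self.genetic_correlation() * np.outer(d, d)


@dataclass
class PhenotypeSet:
    """Simulated phenotypes plus the generating values needed by oracles."""

    Y: np.ndarray                    # (n, k) quantitative value / liability
    Ybin: np.ndarray | None          # (n, k) 0/1 for case-control traits, else NaN
    genetic_values: np.ndarray       # (n, k)
    beta_std: np.ndarray             # (m, k) total per-trait effect, standardized x
    beta_factor_std: np.ndarray      # (m, q) factor effects, standardized x
    beta_specific_std: np.ndarray    # (m, k) specific effects, standardized x
    x_mean: np.ndarray               # (m,) dosage mean used for standardization
    x_sd: np.ndarray                 # (m,) dosage sd used for standardization
    realized_h2: np.ndarray          # (k,)
    factor_causal: np.ndarray        # (m, q) bool
    specific_causal: np.ndarray      # (m, k) bool

    @property
    def beta_dosage(self) -> np.ndarray:
        """Per-dosage total effects (standardized-phenotype scale)."""
        return self.beta_std / self.x_sd[:, None]

    def marginal_specific_dosage(self, panel: "LDPanel") -> np.ndarray:
        """LD-convolved per-dosage specific effects ``(R @ beta_specific) / sd``.

        This is the estimand of a *marginal* per-SNP scan for the
        trait-specific component: a SNP in LD with specific-causal neighbours
        carries their tagged signal even if it is not itself causal.
        """
        return (panel.R @ self.beta_specific_std) / self.x_sd[:, None]

    def marginal_total_dosage(self, panel: "LDPanel") -> np.ndarray:
        """LD-convolved per-dosage total effects (marginal GWAS estimand)."""
        return (panel.R @ self.beta_std) / self.x_sd[:, None]


def _dosage_moments(G: np.ndarray, chunk: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Column means and SDs of an int8 dosage matrix without a full float copy."""
    m = G.shape[1]
    mean = np.empty(m)
    sd = np.empty(m)
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        X = G[:, sl].astype(np.float32)
        mean[sl] = X.mean(axis=0)
        sd[sl] = X.std(axis=0)
    return mean, sd


def _standardized_matmul(G: np.ndarray, B: np.ndarray, mean: np.ndarray,
                         sd: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Compute ``standardize(G) @ B`` without materializing the float copy.

    Uses ``(G @ (B/sd)) - mean'(B/sd)`` so the int8 matrix is only cast, never
    centered element-wise.
    """
    n = G.shape[0]
    B2 = (np.asarray(B, np.float32) / np.asarray(sd, np.float32)[:, None])
    out = np.zeros((n, B.shape[1]), dtype=np.float64)
    for start in range(0, G.shape[1], chunk):
        sl = slice(start, min(start + chunk, G.shape[1]))
        out += G[:, sl].astype(np.float32) @ B2[sl]
    out -= np.asarray(mean, float) @ (np.asarray(B, float) / np.asarray(sd, float)[:, None])
    return out


def simulate_multitrait_phenotypes(genotypes: np.ndarray, arch: TrueArchitecture,
                                   seed: int = 0) -> PhenotypeSet:
    """Generate phenotypes with factor-structured genetic covariance.

    Per-SNP effects are drawn on standardized genotypes; factor scores and
    specific components are rescaled to their target variances in the
    simulated sample, so realized SNP heritability matches ``h2`` up to the
    Monte-Carlo error of the environmental draw.
    """
    n, m = genotypes.shape
    k, q = arch.k, arch.q
    rng_eff = stage_rng(seed, "effects")
    rng_env = stage_rng(seed, "environment")

    x_mean, x_sd = _dosage_moments(genotypes)
    mono = x_sd == 0
    x_sd = np.where(mono, 1.0, x_sd)

    # causal masks per component (explicit masks override fraction draws)
    if arch.factor_causal_mask is not None:
        factor_causal = np.asarray(arch.factor_causal_mask, bool)
        if factor_causal.shape != (m, q):
            raise ValueError("factor_causal_mask must be (m, q)")
    else:
        fc = np.broadcast_to(np.asarray(arch.factor_causal_fraction, float), (q,))
        factor_causal = rng_eff.random((m, q)) < fc
    if arch.specific_causal_mask is not None:
        specific_causal = np.asarray(arch.specific_causal_mask, bool)
        if specific_causal.shape != (m, k):
            raise ValueError("specific_causal_mask must be (m, k)")
    else:
        sc = np.broadcast_to(np.asarray(arch.specific_causal_fraction, float), (k,))
        specific_causal = rng_eff.random((m, k)) < sc

    # correlated factor effects: per-SNP ~ N(0, Phi) on jointly causal SNPs
    Lchol = np.linalg.cholesky(arch.Phi + 1e-12 * np.eye(q))
    beta_factor = (rng_eff.standard_normal((m, q)) @ Lchol.T) * factor_causal
    beta_specific = rng_eff.standard_normal((m, k)) * specific_causal
    beta_factor[mono] = 0.0
    beta_specific[mono] = 0.0

    FS = _standardized_matmul(genotypes, np.hstack([beta_factor, beta_specific]),
                              x_mean, x_sd)
    F, Spec = FS[:, :q], FS[:, q:]
    for f in range(q):
        sdf = F[:, f].std()
        if sdf > 0:
            F[:, f] /= sdf
            beta_factor[:, f] /= sdf
    for t in range(k):
        sds = Spec[:, t].std()
        if arch.Psi[t] <= 0 or sds == 0:
            Spec[:, t] = 0.0
            beta_specific[:, t] = 0.0
        else:
            scale = np.sqrt(arch.Psi[t]) / sds
            Spec[:, t] *= scale
            beta_specific[:, t] *= scale

    G = F @ arch.Lambda.T + Spec                      # unit-variance target
    beta_std = beta_factor @ arch.Lambda.T + beta_specific
    scale_t = np.ones(k)
    for t in range(k):
        sdg = G[:, t].std()
        if arch.h2[t] == 0 or sdg == 0:
            G[:, t] = 0.0
            scale_t[t] = 0.0
        else:
            scale_t[t] = np.sqrt(arch.h2[t]) / sdg
            G[:, t] *= scale_t[t]
    beta_std = beta_std * scale_t

    E = rng_env.standard_normal((n, k)) * np.sqrt(1.0 - arch.h2)
    Y = G + E
    var_y = Y.var(axis=0)
    realized_h2 = np.where(var_y > 0, G.var(axis=0) / var_y, 0.0)

    Ybin = None
    if arch.prevalence is not None:
        prev = np.asarray(arch.prevalence, float)
        Ybin = np.full((n, k), np.nan)
        for t in range(k):
            if np.isfinite(prev[t]):
                thr = np.quantile(Y[:, t], 1.0 - prev[t])
                Ybin[:, t] = (Y[:, t] > thr).astype(float)

    return PhenotypeSet(Y=Y, Ybin=Ybin, genetic_values=G, beta_std=beta_std,
                        beta_factor_std=beta_factor * 1.0, beta_specific_std=beta_specific * scale_t,
                        x_mean=x_mean, x_sd=x_sd, realized_h2=realized_h2,
                        factor_causal=factor_causal, specific_causal=specific_causal)


# ======================================================================
# GWAS
# ======================================================================
def run_gwas(genotypes: np.ndarray, phenotype: np.ndarray, panel: LDPanel,
             covariates: np.ndarray | None = None, binary: bool | None = None,
             trait: str = "trait", chunk: int = 1024) -> SumStats:
    """Per-SNP association scan emitting the canonical SumStats dialect.

    Quantitative traits: simple (or covariate-adjusted) least-squares
    regression of the phenotype on the dosage.  Binary traits: one-step
    score-based logistic regression (effect on the log-odds scale).
    Monomorphic SNPs are emitted with NA effect and flagged in ``meta``.
    P-values are two-sided large-sample normal, so ``|z|`` and ``P`` are
    exactly consistent.
    """
    y = np.asarray(phenotype, float).ravel()
    n = len(y)
    if genotypes.shape[0] != n:
        raise ValueError("genotype/phenotype row mismatch")
    if n < 30:
        raise ValueError("need >= 30 individuals")
    if not genotypes.flags.f_contiguous and genotypes.size > 10_000_000:
        genotypes = np.asfortranarray(genotypes)   # column chunks dominate below
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}

    intercept_only = covariates is None
    if intercept_only:
        C = np.ones((n, 1))
        y_res = y - y.mean()
    else:
        C = np.column_stack([np.ones(n), covariates])
        coef, *_ = np.linalg.lstsq(C, y, rcond=None)
        y_res = y - C @ coef
    ncov = C.shape[1]

    m = genotypes.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    freq = np.full(m, np.nan)
    mono_flags = np.zeros(m, dtype=bool)
    if binary:
        p_bar = y.mean()
        phi = p_bar * (1.0 - p_bar)
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        X = genotypes[:, sl].astype(np.float64)
        freq[sl] = X.mean(axis=0) / 2.0
        # residualize dosages on covariates (plain centering without them)
        if intercept_only:
            Xr = X - X.mean(axis=0)
        else:
            cx = np.linalg.solve(C.T @ C, C.T @ X)
            Xr = X - C @ cx
        sxx = (Xr ** 2).sum(axis=0)
        mono = sxx <= 1e-12
        mono_flags[sl] = mono
        sxx = np.where(mono, np.nan, sxx)
        sxy = Xr.T @ y_res
        if binary:
            # score-based one-step logistic: U = x'(y - p), I = phi * x'x
            b = sxy / (phi * sxx)
            s = 1.0 / np.sqrt(phi * sxx)
        else:
            b = sxy / sxx
            syy = (y_res ** 2).sum()
            dof = max(n - ncov - 1, 1)
            sigma2 = np.maximum(syy - b * sxy, 0.0) / dof
            s = np.sqrt(sigma2 / sxx)
        beta[sl] = b
        se[sl] = s

    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    p = np.where(np.isfinite(z), p, np.nan)
    maf = np.minimum(freq, 1.0 - freq)

    table = pd.DataFrame({
        "SNP": panel.snp_ids,
        "CHR": panel.chrom,
        "BP": panel.positions,
        "A1": "A",
        "A2": "G",
        "BETA": beta,
        "SE": se,
        "P": p,
        "N": n,
        "MAF": maf,
    })
    if mono_flags.any():
        logger.info("run_gwas[%s]: %d monomorphic SNPs emitted with NA effect",
                    trait, int(mono_flags.sum()))
    return SumStats(table, trait=trait,
                    meta={"binary": bool(binary), "n_monomorphic": int(mono_flags.sum())})


# ======================================================================
# Cohort suite
# ======================================================================
@dataclass
class CohortSpec:
    """One GWAS cohort: which trait it measures, its size, its type and its
    overlap with earlier cohorts in the suite.

    ``overlap`` maps an earlier cohort's list index to the fraction of shared
    individuals (of ``min(n_this, n_other)``).  Overlapping individuals share
    genotypes and environmental draws because they are literally the same
    simulated people.
    """

    trait: int
    n: int
    kind: str = "quantitative"           # "quantitative" | "case-control"
    case_fraction: float = 0.5
    overlap: dict = field(default_factory=dict)
    label: str | None = None
    flip_fraction: float = 0.0           # deliberate allele-flip corruption

    def __post_init__(self):
        if self.kind not in ("quantitative", "case-control"):
            raise ValueError(f"unknown cohort kind {self.kind!r}")
        for f in self.overlap.values():
            if not 0 <= f <= 1:
                raise ValueError("overlap fractions must be in [0, 1]")


@dataclass
class GroundTruth:
    """Generating values recorded for parameter-recovery oracles."""

    S_true: np.ndarray
    Lambda: np.ndarray
    Psi: np.ndarray
    Phi: np.ndarray
    h2: np.ndarray
    realized_h2: np.ndarray
    overlap_n: np.ndarray            # (n_cohorts, n_cohorts) shared counts
    pheno_corr: np.ndarray           # (k, k) empirical phenotypic correlations
    expected_cross_intercept: np.ndarray   # (n_cohorts, n_cohorts)
    phenotypes: PhenotypeSet
    cohort_indices: list


@dataclass
class GwasSuite:
    sumstats: list
    truth: GroundTruth
    panel: LDPanel
    arch: TrueArchitecture
    specs: list


def _allocate_cohorts(specs) -> tuple[list, int]:
    """Assign population index arrays honouring the overlap map.

    Case-control cohorts get only their shared (overlap) part here; their
    fresh individuals are drawn stratified by case status once phenotypes
    exist (see :func:`make_gwas_suite`).
    """
    indices, next_free = [], 0
    for c, spec in enumerate(specs):
        shared = []
        for other, frac in spec.overlap.items():
            if not 0 <= other < c:
                raise ValueError("overlap may only reference earlier cohorts")
            ns = int(round(frac * min(spec.n, specs[other].n)))
            shared.append(indices[other][:ns])
        shared = np.unique(np.concatenate(shared)) if shared else np.array([], dtype=int)
        n_fresh = spec.n - len(shared)
        if n_fresh < 0:
            raise ValueError(f"cohort {c}: overlap demands exceed cohort size")
        if spec.kind == "case-control":
            indices.append(shared.astype(int))
        else:
            fresh = np.arange(next_free, next_free + n_fresh)
            next_free += n_fresh
            indices.append(np.concatenate([shared, fresh]).astype(int))
    return indices, next_free


def make_gwas_suite(panel: LDPanel, arch: TrueArchitecture, cohort_specs: list,
                    seed: int = 0, population_size: int | None = None) -> GwasSuite:
    """Simulate a full multi-cohort GWAS study and return the summary
    statistics together with the generating ground truth.

    One population is simulated; cohorts are index sets into it, so overlap
    means shared genotype *and* environment.  Case-control cohorts draw
    cases/controls from the population at the requested case fraction
    (their fresh index allocation is stratified by liability-threshold status).
    """
    indices, demand = _allocate_cohorts(cohort_specs)
    has_cc = any(s.kind == "case-control" for s in cohort_specs)
    pop_n = demand
    if has_cc:
        if arch.prevalence is None:
            raise ValueError("case-control cohorts require arch.prevalence")
        # reserve enough population for the rarest stratified draw
        extra = 0
        for s in cohort_specs:
            if s.kind == "case-control":
                prev = float(arch.prevalence[s.trait])
                extra = max(extra, int(np.ceil(s.n * s.case_fraction / prev * 1.3)))
        pop_n = demand + extra
    if population_size is not None:
        if pop_n > population_size:
            raise ValueError(
                f"total unique-individual demand ({pop_n}) exceeds configured "
                f"population ({population_size})")
        pop_n = population_size

    G = simulate_genotypes(panel, pop_n, seed=seed)
    phen = simulate_multitrait_phenotypes(G, arch, seed=seed)

    sumstats = []
    used_reserve = np.zeros(pop_n, dtype=bool)
    for c, spec in enumerate(cohort_specs):
        label = spec.label or f"{arch.trait_labels[spec.trait]}_c{c}"
        if spec.kind == "case-control":
            status = phen.Ybin[:, spec.trait]
            if np.all(np.isnan(status)):
                raise ValueError(f"cohort {c}: trait {spec.trait} has no prevalence")
            pool = np.arange(demand, pop_n)
            pool = pool[~used_reserve[pool]]
            n_fresh = spec.n - len(indices[c])
            n_case = int(round(n_fresh * spec.case_fraction))
            cases = pool[status[pool] == 1][:n_case]
            controls = pool[status[pool] == 0][:n_fresh - n_case]
            if len(cases) < n_case or len(controls) < n_fresh - n_case:
                raise ValueError(f"cohort {c}: population too small for case/control demand")
            idx = np.concatenate([indices[c], cases, controls]).astype(int)
            used_reserve[cases] = True
            used_reserve[controls] = True
            y = status[idx]
            binary = True
        else:
            idx = indices[c]
            y = phen.Y[idx, spec.trait]
            binary = False
        ss = run_gwas(G[idx], y, panel, binary=binary, trait=label)
        if spec.flip_fraction > 0:
            flip = stage_rng(seed, "misc", extra=c).random(panel.m) < spec.flip_fraction
            t = ss.table
            t.loc[flip, ["A1", "A2"]] = t.loc[flip, ["A2", "A1"]].to_numpy()
            t.loc[flip, "BETA"] = -t.loc[flip, "BETA"]
            t.loc[flip, "MAF"] = 1.0 - t.loc[flip, "MAF"]
            ss.meta["n_flipped"] = int(flip.sum())
        indices[c] = idx
        sumstats.append(ss)

    ncoh = len(cohort_specs)
    overlap_n = np.zeros((ncoh, ncoh), dtype=int)
    expected_int = np.zeros((ncoh, ncoh))
    pheno_corr = np.corrcoef(phen.Y.T) if arch.k > 1 else np.ones((1, 1))
    for a in range(ncoh):
        for b in range(ncoh):
            shared = np.intersect1d(indices[a], indices[b], assume_unique=False)
            overlap_n[a, b] = len(shared)
            if a != b and len(shared):
                ta, tb = cohort_specs[a].trait, cohort_specs[b].trait
                r = np.corrcoef(phen.Y[shared, ta], phen.Y[shared, tb])[0, 1]
                expected_int[a, b] = len(shared) * r / np.sqrt(
                    cohort_specs[a].n * cohort_specs[b].n)

    truth = GroundTruth(S_true=arch.genetic_covariance(), Lambda=arch.Lambda.copy(),
                        Psi=arch.Psi.copy(), Phi=arch.Phi.copy(), h2=arch.h2.copy(),
                        realized_h2=phen.realized_h2, overlap_n=overlap_n,
                        pheno_corr=pheno_corr, expected_cross_intercept=expected_int,
                        phenotypes=phen, cohort_indices=indices)
    return GwasSuite(sumstats=sumstats, truth=truth, panel=panel, arch=arch,
                     specs=list(cohort_specs))


# ======================================================================
# Target cohorts
# ======================================================================
def simulate_target_cohort(panel: LDPanel, truth: GroundTruth, n: int, seed: int = 0,
                           ascertain_cases_for: int | None = None,
                           count_outcomes: bool = True,
                           n_pcs: int = 10) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate an independent target sample sharing the suite's true effects.

    Returns ``(genotypes, phenotypes)`` where the phenotype frame carries one
    column per trait (symptom counts if ``count_outcomes`` else the
    quantitative value), binary ``<trait>_bin`` columns where the architecture
    defines a prevalence, plus ``sex``, ``age`` and ``PC1..PC10`` covariates.

    ``ascertain_cases_for`` restricts the returned sample to liability-threshold
    cases of the given trait (an "all-cases" clinical sample); the population
    is oversampled until ``n`` cases are found.
    """
    phen0 = truth.phenotypes
    k = phen0.beta_std.shape[1]
    rng = stage_rng(seed, "target")

    def _simulate_block(n_block, block_seed):
        G = simulate_genotypes(panel, n_block, seed=block_seed)
        gvals = _standardized_matmul(G, phen0.beta_std, phen0.x_mean, phen0.x_sd)
        E = stage_rng(block_seed, "environment", extra=1).standard_normal((n_block, k))
        h2 = truth.h2
        Y = gvals + E * np.sqrt(np.maximum(1.0 - h2, 0.0))
        return G, Y

    if ascertain_cases_for is None:
        G, Y = _simulate_block(n, seed + 1_000_003)
    else:
        t = ascertain_cases_for
        collected_G, collected_Y = [], []
        got, attempt = 0, 0
        # liability threshold from the discovery population
        thr = np.quantile(phen0.Y[:, t], 1.0 - _trait_prevalence(truth, t))
        while got < n and attempt < 50:
            nb = max(int((n - got) / max(_trait_prevalence(truth, t), 1e-3) * 1.3), 100)
            Gb, Yb = _simulate_block(nb, seed + 1_000_003 + 7 * (attempt + 1))
            mask = Yb[:, t] > thr
            collected_G.append(Gb[mask])
            collected_Y.append(Yb[mask])
            got += int(mask.sum())
            attempt += 1
        if got < n:
            raise RuntimeError("could not ascertain enough cases")
        G = np.concatenate(collected_G)[:n]
        Y = np.concatenate(collected_Y)[:n]

    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(8, 21, size=n)
    pcs = rng.standard_normal((n, n_pcs))
    # mild covariate effects so covariate adjustment is non-trivial
    Yadj = Y + 0.1 * sex[:, None] + 0.01 * (age[:, None] - 14.0)

    data = {}
    for t in range(k):
        name = f"trait{t}"
        if count_outcomes:
            lam = np.exp(0.8 + 0.4 * Yadj[:, t])
            data[name] = rng.poisson(lam).astype(float)
        else:
            data[name] = Yadj[:, t]
        p_t = _trait_prevalence_or_nan(truth, t)
        if np.isfinite(p_t):
            thr = np.quantile(Yadj[:, t], 1.0 - p_t)
            data[f"{name}_bin"] = (Yadj[:, t] > thr).astype(float)
    data["sex"] = sex
    data["age"] = age
    for j in range(n_pcs):
        data[f"PC{j + 1}"] = pcs[:, j]
    return G, pd.DataFrame(data)


def _trait_prevalence_or_nan(truth: GroundTruth, t: int) -> float:
    if truth.phenotypes.Ybin is not None:
        col = truth.phenotypes.Ybin[:, t]
        if np.any(np.isfinite(col)):
            return float(np.nanmean(col))
    return float("nan")


def _trait_prevalence(truth: GroundTruth, t: int) -> float:
    p = _trait_prevalence_or_nan(truth, t)
    if not np.isfinite(p):
        return 0.2   # default ascertainment prevalence for quantitative traits
    return p
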