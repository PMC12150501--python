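"""LD score regression: heritabilities, genetic covariances, overlap
intercepts, and their block-jackknife sampling covariance.

The central products are a per-SNP LD score vector (``l_j = sum_k r^2_jk``
over neighbouring SNPs) and a :class:`CovStructure` holding the k x k
genetic covariance matrix ``S`` (diagonal = SNP heritabilities), the
sampling covariance ``V`` of its unique elements from a contiguous block
jackknife, and the intercept matrix ``I`` whose off-diagonal elements
encode sample overlap.  ``S``/``V``/``I`` are the inputs to genomic SEM.

Model, for SNP j with LD score l_j (cross-trait form; the univariate case
regresses chi^2 on ``N l_j / M``)::

    E[z_1j z_2j] = sqrt(N1 N2) * rho_g * l_j / M  +  intercept

so the regression slope is the genetic covariance and the free intercept
absorbs overlap (``Ns * r_pheno / sqrt(N1 N2)``) or, for the univariate
regression, confounding (expected 1 without it).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import HarmonizedSet, SumStats

logger = logging.getLogger(__name__)

__all__ = [
    "LDScores", "CovStructure", "LDSCResults", "LDScoreRegression",
    "compute_ld_scores", "fit_ldsc_pair", "build_cov_structure",
    "genetic_correlation",
]


# ======================================================================
@dataclass
class LDScores:
    """Per-SNP LD scores plus the window definition that produced them."""

    l2: np.ndarray
    positions: np.ndarray
    snp_ids: np.ndarray
    window_kb: float
    M: int
    source: str = "true_R"    # provenance: "true_R" | "genotypes"

    def __post_init__(self):
        self.l2 = np.asarray(self.l2, float)
        if np.any(~np.isfinite(self.l2)):
            raise ValueError("non-finite LD scores")
        if np.any(self.l2 < 1.0 - 1e-9):
            raise ValueError("LD scores below 1 (self-r^2 must be included)")

    def write(self, path) -> None:
        pd.DataFrame({"SNP": self.snp_ids, "CHR": 1, "BP": self.positions,
                      "L2": self.l2}).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, window_kb=float("nan")) -> "LDScores":
        df = pd.read_csv(path, sep="\t")
        return cls(l2=df["L2"].to_numpy(), positions=df["BP"].to_numpy(),
                   snp_ids=df["SNP"].to_numpy(dtype=str), window_kb=window_kb,
                   M=len(df), source="file")


def compute_ld_scores(panel=None, genotypes: np.ndarray | None = None,
                      window_kb: float = 1000.0, adjust: bool = True) -> LDScores:
    """LD scores from the true panel correlation matrix or from reference
    genotypes.

    With genotypes, squared sample correlations get the small-sample bias
    adjustment ``r2_adj = r2 - (1 - r2) / (n - 2)`` when ``adjust``.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be > 0")
    if panel is None and genotypes is None:
        raise ValueError("provide a panel or genotypes")
    if genotypes is not None:
        n, m = genotypes.shape
        if adjust and n < 3:
            raise ValueError("need n >= 3 for the bias adjustment")
        X = genotypes.astype(np.float64)
        sd = X.std(axis=0)
        keep_sd = np.where(sd == 0, 1.0, sd)
        Xs = (X - X.mean(axis=0)) / keep_sd
        R2 = (Xs.T @ Xs / n) ** 2
        if adjust:
            R2 = R2 - (1.0 - R2) / (n - 2)
        positions = panel.positions if panel is not None else np.arange(m) * 5000 + 1
        snp_ids = panel.snp_ids if panel is not None else np.array(
            [f"rs{i+1}" for i in range(m)])
        source = "genotypes"
    else:
        # block-diagonal true R: accumulate within blocks, never densify
        positions = panel.positions
        snp_ids = panel.snp_ids
        m = panel.m
        window_bp = window_kb * 1000.0
        pos = np.asarray(positions, float)
        l2 = np.empty(m)
        for sl, rho in zip(panel.block_slices, panel.block_rhos):
            s = sl.stop - sl.start
            idx = np.arange(s)
            R2b = (rho ** np.abs(idx[:, None] - idx[None, :])) ** 2
            pb = pos[sl]
            lo = np.searchsorted(pb, pb - window_bp, side="left")
            hi = np.searchsorted(pb, pb + window_bp, side="right")
            for j in range(s):
                l2[sl.start + j] = R2b[j, lo[j]:hi[j]].sum()
        return LDScores(l2=l2, positions=np.asarray(positions),
                        snp_ids=np.asarray(snp_ids), window_kb=window_kb, M=m,
                        source="true_R")

    window_bp = window_kb * 1000.0
    l2 = np.empty(m)
    pos = np.asarray(positions, float)
    lo = np.searchsorted(pos, pos - window_bp, side="left")
    hi = np.searchsorted(pos, pos + window_bp, side="right")
    for j in range(m):
        l2[j] = R2[j, lo[j]:hi[j]].sum() - R2[j, j] + 1.0  # self term exactly 1
    # the unbiased r^2 adjustment can dip a window sum below the self term
    l2 = np.maximum(l2, 1.0)
    return LDScores(l2=l2, positions=np.asarray(positions), snp_ids=np.asarray(snp_ids),
                    window_kb=window_kb, M=m, source=source)


# ======================================================================
@dataclass
class LDSCResults:
    """Fitted LD score regression: slope (h2 or rho_g), free intercept, and
    leave-one-block-out machinery for the jackknife covariance."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_pseudovalues: np.ndarray
    intercept_pseudovalues: np.ndarray
    n_snps: int
    n_blocks: int
    kind: str                  # "h2" | "rhog"
    mean_chisq: float = float("nan")

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats
        zq = stats.norm.ppf(0.5 + level / 2)
        return self.slope - zq * self.slope_se, self.slope + zq * self.slope_se

    def summary(self) -> str:
        lo, hi = self.slope_ci()
        name = "h2" if self.kind == "h2" else "rho_g"
        return (f"LD score regression ({self.kind}): {name} = {self.slope:.4f} "
                f"(SE {self.slope_se:.4f}, 95% CI [{lo:.4f}, {hi:.4f}]), "
                f"intercept = {self.intercept:.4f} (SE {self.intercept_se:.4f}), "
                f"{self.n_snps} SNPs, {self.n_blocks} jackknife blocks")


class LDScoreRegression:
    """Weighted LD score regression for one trait pair (statsmodels-style:
    construct from data, then :meth:`fit`).

    Parameters
    ----------
    z1, z2 : per-SNP z-scores on a shared SNP universe (pass the same array
        twice, or ``z2=None``, for a univariate heritability fit).
    n1, n2 : per-SNP sample sizes.
    ld : :class:`LDScores` on the same universe.
    n_blocks : contiguous jackknife blocks (200 is the field convention).
    chisq_cap : drop SNPs with chi^2 above ``max(80, 0.001 N)`` (None disables).
    """

    def __init__(self, z1, n1, ld: LDScores, z2=None, n2=None, n_blocks: int = 200,
                 intercept_free: bool = True, chisq_cap: bool = True,
                 mask: np.ndarray | None = None):
        self.z1 = np.asarray(z1, float)
        self.z2 = self.z1 if z2 is None else np.asarray(z2, float)
        self.univariate = self.z2 is self.z1 or np.array_equal(self.z1, self.z2)
        self.n1 = np.broadcast_to(np.asarray(n1, float), self.z1.shape)
        self.n2 = self.n1 if n2 is None else np.broadcast_to(np.asarray(n2, float),
                                                             self.z1.shape)
        self.ld = ld
        self.n_blocks = int(n_blocks)
        self.intercept_free = intercept_free
        self.chisq_cap = chisq_cap
        if mask is None:
            mask = np.ones(len(self.z1), dtype=bool)
        self.mask = mask & np.isfinite(self.z1) & np.isfinite(self.z2)
        if self.chisq_cap:
            self.mask &= self.default_cap_mask()
        if self.mask.sum() <= self.n_blocks:
            raise ValueError("fewer usable SNPs than jackknife blocks")

    def default_cap_mask(self) -> np.ndarray:
        cap1 = np.maximum(80.0, 0.001 * self.n1)
        cap2 = np.maximum(80.0, 0.001 * self.n2)
        ok = (self.z1 ** 2 <= cap1) & (self.z2 ** 2 <= cap2)
        ncut = int((~ok & np.isfinite(self.z1) & np.isfinite(self.z2)).sum())
        if ncut:
            logger.info("ldsc: chi^2 cap removed %d SNPs", ncut)
        return ok

    # ------------------------------------------------------------------
    def _design(self):
        keep = self.mask
        l2 = np.maximum(self.ld.l2[keep], 1.0)
        M = self.ld.M
        if self.univariate:
            y = self.z1[keep] ** 2
            x = self.n1[keep] * l2 / M
        else:
            y = self.z1[keep] * self.z2[keep]
            x = np.sqrt(self.n1[keep] * self.n2[keep]) * l2 / M
        return x, y, l2

    def _weights(self, x, l2, slope, intercept):
        """Heteroskedasticity weights 1 / (l * var_j) from current estimates."""
        if self.univariate:
            ey = np.maximum(slope * x + intercept, 0.05)
            var = 2.0 * ey ** 2
        else:
            keep = self.mask
            e1 = np.maximum(self._h1 * self.n1[keep] * l2 / self.ld.M + 1.0, 0.05)
            e2 = np.maximum(self._h2 * self.n2[keep] * l2 / self.ld.M + 1.0, 0.05)
            ec = slope * x + intercept
            var = e1 * e2 + ec ** 2
        return 1.0 / (l2 * np.maximum(var, 1e-12))

    @staticmethod
    def _wls(x, y, w, free_intercept, fixed_intercept=1.0):
        if free_intercept:
            X = np.column_stack([x, np.ones_like(x)])
            A = X.T @ (X * w[:, None])
            c = X.T @ (w * y)
            theta = np.linalg.solve(A, c)
            return theta[0], theta[1]
        A = float(np.sum(w * x * x))
        c = float(np.sum(w * x * (y - fixed_intercept)))
        return c / A, fixed_intercept

    def fit(self) -> LDSCResults:
        x, y, l2 = self._design()
        if not self.univariate:
            # quick univariate slopes feed the cross-trait weight formula
            self._h1 = self._quick_h2(self.z1, self.n1)
            self._h2 = self._quick_h2(self.z2, self.n2)
        fixed = 1.0 if self.univariate else 0.0
        w = 1.0 / l2
        slope, intercept = self._wls(x, y, w, self.intercept_free, fixed)
        for _ in range(2):   # iteratively reweighted, two passes
            w = self._weights(x, l2, slope, intercept)
            slope, intercept = self._wls(x, y, w, self.intercept_free, fixed)

        # --- block jackknife on the final weights -------------------------
        B = self.n_blocks
        mkeep = int(self.mask.sum())
        edges = np.linspace(0, mkeep, B + 1).astype(int)
        X = np.column_stack([x, np.ones_like(x)]) if self.intercept_free else x[:, None]
        yy = y if self.intercept_free else y - fixed
        Xw = X * w[:, None]
        A_tot = X.T @ Xw
        c_tot = Xw.T @ yy
        theta_hat = np.linalg.solve(A_tot, c_tot)
        slope_ps = np.empty(B)
        int_ps = np.empty(B)
        for b in range(B):
            sl = slice(edges[b], edges[b + 1])
            A_b = X[sl].T @ Xw[sl]
            c_b = Xw[sl].T @ yy[sl]
            theta_b = np.linalg.solve(A_tot - A_b, c_tot - c_b)
            ps = B * theta_hat - (B - 1) * theta_b
            slope_ps[b] = ps[0]
            int_ps[b] = ps[1] if self.intercept_free else fixed
        slope_se = float(np.std(slope_ps, ddof=1) / np.sqrt(B))
        int_se = float(np.std(int_ps, ddof=1) / np.sqrt(B)) if self.intercept_free else 0.0

        res = LDSCResults(
            slope=float(theta_hat[0]),
            intercept=float(theta_hat[1]) if self.intercept_free else fixed,
            slope_se=slope_se, intercept_se=int_se,
            slope_pseudovalues=slope_ps, intercept_pseudovalues=int_ps,
            n_snps=mkeep, n_blocks=B,
            kind="h2" if self.univariate else "rhog",
            mean_chisq=float(np.mean(self.z1[self.mask] ** 2)) if self.univariate
            else float("nan"),
        )
        if self.univariate and res.slope < 0:
            logger.warning("ldsc: negative heritability estimate (%.4f)", res.slope)
        return res

    def _quick_h2(self, z, n) -> float:
        keep = self.mask
        l2 = np.maximum(self.ld.l2[keep], 1.0)
        x = n[keep] * l2 / self.ld.M
        s, _ = self._wls(x, z[keep] ** 2, 1.0 / l2, True)
        return max(s, 0.0)


def fit_ldsc_pair(ss1: SumStats, ss2: SumStats, ld: LDScores,
                  intercept_free: bool = True, n_blocks: int = 200,
                  chisq_cap: bool = True) -> LDSCResults:
    """Univariate (``ss2 is ss1``) or cross-trait LDSC fit on harmonized
    sumstats sharing the LD-score SNP universe."""
    if len(ss1) != len(ld.l2) or len(ss2) != len(ld.l2):
        raise ValueError("sumstats and LD scores must share the SNP universe")
    z2 = None if ss2 is ss1 else ss2.z
    n2 = None if ss2 is ss1 else ss2.table["N"].to_numpy(float)
    model = LDScoreRegression(ss1.z, ss1.table["N"].to_numpy(float), ld,
                              z2=z2, n2=n2, n_blocks=n_blocks,
                              intercept_free=intercept_free, chisq_cap=chisq_cap)
    return model.fit()


# ======================================================================
@dataclass
class CovStructure:
    """Genetic covariance matrix S, jackknife sampling covariance V of its
    unique (upper-triangle) elements, intercept matrix I, SNP count M."""

    S: np.ndarray
    V: np.ndarray
    I: np.ndarray
    M: int
    traits: list

    def __post_init__(self):
        k = self.S.shape[0]
        p = k * (k + 1) // 2
        if self.V.shape != (p, p):
            raise ValueError(f"V must be {p}x{p} for k={k}")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("S must be symmetric")

    @property
    def k(self) -> int:
        return self.S.shape[0]

    def element_index(self, i: int, j: int) -> int:
        """Position of S[i, j] within the vech/V ordering."""
        iu = np.triu_indices(self.k)
        i, j = min(i, j), max(i, j)
        return int(np.flatnonzero((iu[0] == i) & (iu[1] == j))[0])

    # -- round-trippable structured-text serialization ------------------
    def to_json(self, path=None) -> str:
        payload = {
            "traits": list(self.traits),
            "M": int(self.M),
            "S": self.S.tolist(),
            "V": self.V.tolist(),
            "I": self.I.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CovStructure":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(S=np.array(payload["S"]), V=np.array(payload["V"]),
                   I=np.array(payload["I"]), M=int(payload["M"]),
                   traits=list(payload["traits"]))


def _shrink_correlation(pseudo: np.ndarray) -> np.ndarray:
    """Jackknife covariance with Ledoit-Wolf shrinkage of the correlation
    structure (diagonal variances preserved).

    With p = k(k+1)/2 elements estimated from B blocks, the raw sample
    covariance is ill-conditioned whenever p is not much smaller than B, and
    its inverse -- used in the model chi-square -- explodes along the
    distorted small eigenvalues.  Shrinking only the off-diagonal correlation
    toward zero fixes the conditioning without touching the marginal
    sampling variances (so element-wise SEs are unchanged).
    """
    from sklearn.covariance import LedoitWolf

    B = pseudo.shape[0]
    sd = pseudo.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (pseudo - pseudo.mean(axis=0)) / sd
    alpha = LedoitWolf().fit(Z).shrinkage_
    C = np.corrcoef(pseudo, rowvar=False)
    C = np.atleast_2d(C)
    C_shrunk = (1.0 - alpha) * C + alpha * np.eye(C.shape[0])
    V = C_shrunk * np.outer(sd, sd) / B
    return (V + V.T) / 2


def build_cov_structure(hset: HarmonizedSet, ld: LDScores, n_blocks: int = 200,
                        chisq_cap: bool = True, intercept_free: bool = True,
                        shrink_v: bool = False) -> CovStructure:
    """Assemble S, V and I from all k(k+1)/2 pairwise LDSC fits.

    All fits share one SNP mask (the intersection of the per-trait chi^2 cap
    masks) and one contiguous block partition, so the stacked pseudovalues
    are aligned and their jackknife covariance is a valid V.  The block
    partition must respect the LD correlation length (blocks shorter than an
    LD block are mutually correlated and V is then underestimated).
    ``shrink_v`` applies diagonal-preserving Ledoit-Wolf shrinkage to V's
    correlation structure; recommended when k(k+1)/2 approaches ``n_blocks``.
    """
    k = hset.k
    if k < 2:
        raise ValueError("need k >= 2 traits")
    Z = hset.zscores()
    N = hset.nobs()
    mask = np.all(np.isfinite(Z), axis=1)
    if chisq_cap:
        caps = np.maximum(80.0, 0.001 * N)
        mask &= np.all(Z ** 2 <= caps, axis=1)

    iu = np.triu_indices(k)
    p = len(iu[0])
    S = np.zeros((k, k))
    I = np.zeros((k, k))
    pseudo = np.zeros((n_blocks, p))
    for e, (i, j) in enumerate(zip(*iu)):
        try:
            model = LDScoreRegression(
                Z[:, i], N[:, i], ld,
                z2=None if i == j else Z[:, j],
                n2=None if i == j else N[:, j],
                n_blocks=n_blocks, intercept_free=intercept_free,
                chisq_cap=False, mask=mask.copy())
            res = model.fit()
        except Exception as err:
            raise RuntimeError(
                f"LDSC failed for trait pair ({hset.traits[i]}, {hset.traits[j]}): {err}"
            ) from err
        S[i, j] = S[j, i] = res.slope
        I[i, j] = I[j, i] = res.intercept
        pseudo[:, e] = res.slope_pseudovalues
    if shrink_v:
        V = _shrink_correlation(pseudo)
    else:
        V = np.atleast_2d(np.cov(pseudo, rowvar=False, ddof=1)) / n_blocks
    return CovStructure(S=S, V=V, I=I, M=ld.M, traits=list(hset.traits))


def genetic_correlation(cov: CovStructure, i: int, j: int) -> tuple[float, float]:
    """``rg = S_ij / sqrt(S_ii S_jj)`` with a delta-method SE from V.

    Returns ``(nan, nan)`` with a warning when a heritability is non-positive.
    """
    hi, hj, sij = cov.S[i, i], cov.S[j, j], cov.S[i, j]
    if i == j:
        return 1.0, 0.0
    if hi <= 0 or hj <= 0:
        logger.warning("genetic_correlation: non-positive heritability (trait %d/%d)", i, j)
        return float("nan"), float("nan")
    rg = sij / np.sqrt(hi * hj)
    g = np.zeros(cov.V.shape[0])
    g[cov.element_index(i, j)] = 1.0 / np.sqrt(hi * hj)
    g[cov.element_index(i, i)] = -rg / (2.0 * hi)
    g[cov.element_index(j, j)] = -rg / (2.0 * hj)
    var = float(g @ cov.V @ g)
    return float(rg), float(np.sqrt(max(var, 0.0)))
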