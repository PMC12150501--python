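"""Genomic structural equation modeling on an LDSC covariance structure.

The measurement model is a confirmatory factor model for the genetic
covariance matrix ``S``::

    Sigma(theta) = Lambda Phi Lambda' + Theta

with free loadings where the pattern says so, free factor correlations
(unit factor variances for identification, so SNP->factor paths share a
scale), and free diagonal residual variances bounded at zero.  Estimation
is diagonally weighted least squares:

    F(theta) = (s - sigma(theta))' D^{-1} (s - sigma(theta)),   D = diag(V)

with sandwich standard errors using the full sampling covariance ``V``, a
V-weighted residual quadratic form as the model chi-square, AIC = chi2 +
2 * n_free, CFI against an independence model fitted the same way, and
SRMR on the correlation scale.

Per-SNP "edges" extend the fitted model: the covariance matrix is augmented
with a SNP row (``cov(SNP, trait_t) = beta_t * 2p(1-p)``) and refitted with
all measurement parameters fixed, leaving free one SNP->factor path and one
SNP->residual path per designated trait.  Because the measurement part is
fixed, the refit is a small weighted least-squares problem with a closed
form, solved for every SNP at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldsc import CovStructure
from .rotation import promax
from .sumstats import HarmonizedSet, SumStats

logger = logging.getLogger(__name__)

__all__ = [
    "smooth_pd", "EFAResult", "efa_extract", "SEMModel", "cfa_spec_from_efa",
    "GenomicSEM", "GenomicSEMResults", "fit_cfa_dwls", "compare_cfa_models",
    "SNPEdgeResult", "GENOME_WIDE_SIG",
]

#: two-sided genome-wide significance threshold used for locus counting
GENOME_WIDE_SIG = 5e-8


class SEMFitError(RuntimeError):
    pass


# ======================================================================
def smooth_pd(S: np.ndarray, V: np.ndarray | None = None,
              eps: float = 1e-6) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Project S to positive definiteness by eigenvalue clipping on the
    correlation scale, rescaling back to the original variances.

    Returns ``(S', V, max |S - S'|)``.  ``V`` is passed through unchanged:
    rescaling sampling variances element-wise is ill-defined when smoothing
    zeroes or flips an element, and the diagnostic ``max |S - S'|`` is the
    interpretable measure of how far the data were moved.
    """
    S = np.asarray(S, float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    d = np.sqrt(np.diag(S))
    if np.any(d <= 0):
        raise ValueError("smooth_pd requires positive diagonal (heritabilities)")
    R = S / np.outer(d, d)
    w, U = np.linalg.eigh((R + R.T) / 2)
    if w.min() >= eps:
        return S.copy(), V, 0.0
    w_clip = np.maximum(w, eps)
    R1 = (U * w_clip) @ U.T
    dr = np.sqrt(np.diag(R1))
    R1 = R1 / np.outer(dr, dr)
    S1 = R1 * np.outer(d, d)
    S1 = (S1 + S1.T) / 2
    change = float(np.abs(S - S1).max())
    logger.info("smooth_pd: max |S - S'| = %.3e", change)
    return S1, V, change


# ======================================================================
@dataclass
class EFAResult:
    """Oblique exploratory factor solution on the correlation-scaled S."""

    n_factors: int
    loadings: np.ndarray        # (k, q) promax pattern matrix
    factor_corr: np.ndarray     # (q, q)
    eigenvalues: np.ndarray     # of the correlation matrix, descending
    communalities: np.ndarray
    heywood: bool = False
    traits: list = field(default_factory=list)

    @property
    def n_eigen_gt1(self) -> int:
        return int((self.eigenvalues > 1.0).sum())


def efa_extract(S: np.ndarray, n_factors: int, traits: list | None = None) -> EFAResult:
    """Principal-axis extraction with promax rotation (2-5 factors).

    Operates on the correlation-scaled S; Heywood cases (communality >= 1)
    are flagged, not fatal.
    """
    from statsmodels.multivariate.factor import Factor

    if not 2 <= n_factors <= 5:
        raise ValueError("n_factors must be in 2..5")
    S = np.asarray(S, float)
    k = S.shape[0]
    if n_factors >= k:
        raise ValueError("n_factors must be < number of traits")
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    fa = Factor(corr=R, n_factor=n_factors, method="pa")
    res = fa.fit()
    raw = np.asarray(res.loadings)
    if raw.ndim != 2 or raw.shape[1] < n_factors:
        # no common variance: extraction returns fewer columns; pad with zeros
        full = np.zeros((k, n_factors))
        if raw.size:
            full[:, :raw.shape[1]] = raw
        raw = full
    comm = (raw ** 2).sum(axis=1)
    heywood = bool(np.any(comm >= 1.0 - 1e-9))
    if heywood:
        logger.warning("efa_extract: Heywood case flagged (communality >= 1)")
    pattern, _, phi = promax(raw)
    return EFAResult(n_factors=n_factors, loadings=pattern, factor_corr=phi,
                     eigenvalues=eigenvalues, communalities=comm, heywood=heywood,
                     traits=list(traits) if traits is not None else
                     [f"trait{i}" for i in range(k)])


# ======================================================================
@dataclass
class SEMModel:
    """Confirmatory factor pattern: which loadings are free.

    Factor variances are fixed at 1, factor correlations and residual
    variances are free.
    """

    pattern: np.ndarray                  # (k, q) bool
    traits: list
    factors: list

    def __post_init__(self):
        self.pattern = np.asarray(self.pattern, bool)
        k, q = self.pattern.shape
        if np.any(self.pattern.sum(axis=1) < 1):
            orphans = [self.traits[i] for i in np.flatnonzero(self.pattern.sum(axis=1) < 1)]
            raise ValueError(f"traits load on no factor: {orphans}")
        if self.n_free > k * (k + 1) // 2:
            raise ValueError("model not identified: more free parameters than moments")

    @property
    def k(self) -> int:
        return self.pattern.shape[0]

    @property
    def q(self) -> int:
        return self.pattern.shape[1]

    @property
    def n_free(self) -> int:
        return int(self.pattern.sum()) + self.q * (self.q - 1) // 2 + self.k

    @classmethod
    def unidimensional(cls, traits: list) -> "SEMModel":
        k = len(traits)
        return cls(pattern=np.ones((k, 1), bool), traits=list(traits), factors=["F1"])

    @classmethod
    def from_loading_map(cls, loading_map: dict, traits: list) -> "SEMModel":
        """Build from ``{factor_name: [trait names]}`` (cross-loadings allowed)."""
        factors = list(loading_map)
        pattern = np.zeros((len(traits), len(factors)), bool)
        for f, members in loading_map.items():
            for t in members:
                pattern[traits.index(t), factors.index(f)] = True
        return cls(pattern=pattern, traits=list(traits), factors=factors)

    def describe(self) -> str:
        lines = []
        for f in range(self.q):
            members = [self.traits[t] for t in np.flatnonzero(self.pattern[:, f])]
            lines.append(f"{self.factors[f]}: " + " + ".join(members))
        return "\n".join(lines)


def cfa_spec_from_efa(efa: EFAResult, cutoff: float = 0.30) -> SEMModel:
    """Free a loading wherever the rotated EFA loading exceeds the cutoff in
    absolute value; a trait with no loading above the cutoff is assigned to
    its highest-|loading| factor; factors left with no indicator are dropped."""
    L = efa.loadings
    pattern = np.abs(L) > cutoff
    for t in np.flatnonzero(pattern.sum(axis=1) == 0):
        pattern[t, np.argmax(np.abs(L[t]))] = True
    keep = pattern.sum(axis=0) > 0
    if not keep.all():
        logger.warning("cfa_spec_from_efa: dropped %d factor(s) with no indicators",
                       int((~keep).sum()))
    pattern = pattern[:, keep]
    factors = [f"F{f + 1}" for f in range(pattern.shape[1])]
    return SEMModel(pattern=pattern, traits=list(efa.traits), factors=factors)


# ======================================================================
class GenomicSEM:
    """DWLS confirmatory factor model for a genetic covariance structure.

    Parameters
    ----------
    cov : CovStructure from :func:`pgsem.ldsc.build_cov_structure` (or built
        analytically); S is PD-smoothed on construction.
    model : the loading pattern.
    """

    def __init__(self, cov: CovStructure, model: SEMModel, smooth: bool = True,
                 smooth_eps: float = 1e-6):
        if cov.k != model.k:
            raise ValueError("covariance structure / model dimension mismatch")
        self.cov = cov
        self.model = model
        if smooth:
            S1, _, change = smooth_pd(cov.S, cov.V, eps=smooth_eps)
        else:
            S1, change = cov.S.copy(), 0.0
        self.S = S1
        self.smooth_change = change
        self.V = cov.V
        k = model.k
        self._iu = np.triu_indices(k)
        self.s = self.S[self._iu]
        D = np.diag(self.V).copy()
        floor = max(D.max() * 1e-12, 1e-30)
        self.D = np.maximum(D, floor)
        self._wsqrt = 1.0 / np.sqrt(self.D)
        # free-parameter bookkeeping
        self._load_idx = np.argwhere(model.pattern)          # rows: (t, f)
        q = model.q
        self._phi_idx = [(f, g) for f in range(q) for g in range(f + 1, q)]
        self.n_free = len(self._load_idx) + len(self._phi_idx) + k

    # ------------------------------------------------------------------
    def _unpack(self, theta):
        k, q = self.model.k, self.model.q
        nl = len(self._load_idx)
        Lam = np.zeros((k, q))
        Lam[self._load_idx[:, 0], self._load_idx[:, 1]] = theta[:nl]
        Phi = np.eye(q)
        for e, (f, g) in enumerate(self._phi_idx):
            Phi[f, g] = Phi[g, f] = theta[nl + e]
        Theta = theta[nl + len(self._phi_idx):]
        return Lam, Phi, Theta

    def _sigma_vec(self, theta):
        Lam, Phi, Theta = self._unpack(theta)
        Sigma = Lam @ Phi @ Lam.T + np.diag(Theta)
        return Sigma[self._iu]

    def _jacobian(self, theta):
        """Analytic d sigma / d theta, (p*, n_free)."""
        Lam, Phi, _ = self._unpack(theta)
        k = self.model.k
        iu = self._iu
        nl = len(self._load_idx)
        J = np.zeros((len(self.s), self.n_free))
        LP = Lam @ Phi
        for c, (t, f) in enumerate(self._load_idx):
            M = np.zeros((k, k))
            M[t, :] += LP[:, f]
            M[:, t] += LP[:, f]
            J[:, c] = M[iu]
        for e, (f, g) in enumerate(self._phi_idx):
            M = np.outer(Lam[:, f], Lam[:, g])
            M = M + M.T
            J[:, nl + e] = M[iu]
        base = nl + len(self._phi_idx)
        diag_pos = np.flatnonzero(iu[0] == iu[1])
        for t in range(k):
            J[diag_pos[t], base + t] = 1.0
        return J

    def _residuals(self, theta):
        return (self._sigma_vec(theta) - self.s) * self._wsqrt

    def _res_jac(self, theta):
        return self._jacobian(theta) * self._wsqrt[:, None]

    def _start(self, rng=None):
        k = self.model.k
        s_tt = np.diag(self.S)
        lam0 = np.array([0.7 * np.sqrt(s_tt[t]) / np.sqrt(max(self.model.pattern[t].sum(), 1))
                         for t, f in self._load_idx])
        phi0 = np.full(len(self._phi_idx), 0.2)
        th0 = 0.5 * s_tt
        theta = np.concatenate([lam0, phi0, th0])
        if rng is not None:
            theta = theta * rng.uniform(0.5, 1.5, size=theta.size)
            nl = len(self._load_idx)
            theta[nl:nl + len(phi0)] = rng.uniform(-0.5, 0.5, size=len(phi0))
        return theta

    def _bounds(self):
        nl = len(self._load_idx)
        np_phi = len(self._phi_idx)
        k = self.model.k
        lo = np.concatenate([np.full(nl, -np.inf), np.full(np_phi, -0.999), np.zeros(k)])
        hi = np.concatenate([np.full(nl, np.inf), np.full(np_phi, 0.999),
                             np.full(k, np.inf)])
        return lo, hi

    # ------------------------------------------------------------------
    def fit(self, n_restarts: int = 4, seed: int = 0,
            raise_on_failure: bool = True) -> "GenomicSEMResults":
        """Minimize the DWLS objective from several starts; keep the best."""
        rng = np.random.default_rng(seed)
        lo, hi = self._bounds()
        best = None
        for r in range(n_restarts + 1):
            x0 = self._start(None if r == 0 else rng)
            x0 = np.clip(x0, lo + 1e-9, np.where(np.isfinite(hi), hi - 1e-9, x0))
            try:
                res = optimize.least_squares(
                    self._residuals, x0, jac=self._res_jac, bounds=(lo, hi),
                    method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=3000)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise SEMFitError("DWLS optimization failed from all starts")
        grad = self._res_jac(best.x).T @ self._residuals(best.x)
        grad_norm = float(np.linalg.norm(grad))
        converged = bool(best.success)
        if not converged and raise_on_failure and grad_norm > 1e-3:
            raise SEMFitError(
                f"non-convergence: F={2 * best.cost:.6g}, |grad|={grad_norm:.3g}")
        return GenomicSEMResults(model_obj=self, theta=best.x,
                                 cost=float(2 * best.cost), grad_norm=grad_norm,
                                 converged=converged)


@dataclass
class GenomicSEMResults:
    """Fitted genomic SEM: estimates, sandwich SEs, fit indices."""

    model_obj: GenomicSEM
    theta: np.ndarray
    cost: float
    grad_norm: float
    converged: bool

    def __post_init__(self):
        gs = self.model_obj
        self.model = gs.model
        self.Lambda, self.Phi, Theta = gs._unpack(self.theta)
        self.Theta = np.asarray(Theta)
        self.implied = self.Lambda @ self.Phi @ self.Lambda.T + np.diag(self.Theta)
        self._compute_se()
        self._compute_fit()

    # ------------------------------------------------------------------
    def _compute_se(self):
        gs = self.model_obj
        J = gs._jacobian(self.theta)
        W = 1.0 / gs.D
        A = J.T @ (J * W[:, None])
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
        JW = J * W[:, None]
        middle = JW.T @ gs.V @ JW
        covp = Ainv @ middle @ Ainv
        self.param_cov = covp
        self.bse = np.sqrt(np.maximum(np.diag(covp), 0.0))

    def _compute_fit(self):
        gs = self.model_obj
        k = self.model.k
        s = gs.s
        r = s - self.implied[gs._iu]
        W = np.linalg.pinv((gs.V + gs.V.T) / 2, rcond=1e-10)
        pstar = len(s)
        self.chi2 = float(r @ W @ r)
        self.df = int(pstar - gs.n_free)
        self.pvalue = float(stats.chi2.sf(self.chi2, self.df)) if self.df > 0 else float("nan")
        self.aic = self.chi2 + 2.0 * gs.n_free
        # independence model: diagonal free (fits s_ii exactly under D weights)
        r_ind = s.copy()
        diag_pos = gs._iu[0] == gs._iu[1]
        r_ind[diag_pos] = 0.0
        chi2_ind = float(r_ind @ W @ r_ind)
        df_ind = pstar - k
        num = max(self.chi2 - self.df, 0.0)
        den = max(chi2_ind - df_ind, num)
        self.cfi = 1.0 - num / den if den > 0 else 1.0
        # SRMR on the correlation scale
        d = np.sqrt(np.diag(gs.S))
        resid_std = (gs.S - self.implied) / np.outer(d, d)
        self.srmr = float(np.sqrt(np.mean(resid_std[gs._iu] ** 2)))

    # ------------------------------------------------------------------
    @property
    def n_free(self) -> int:
        return self.model_obj.n_free

    @property
    def standardized_loadings(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.implied))
        return self.Lambda / sd[:, None]

    def param_table(self) -> pd.DataFrame:
        gs = self.model_obj
        rows = []
        nl = len(gs._load_idx)
        for c, (t, f) in enumerate(gs._load_idx):
            rows.append({"param": f"{self.model.traits[t]}~{self.model.factors[f]}",
                         "kind": "loading", "est": self.theta[c], "se": self.bse[c]})
        for e, (f, g) in enumerate(gs._phi_idx):
            rows.append({"param": f"{self.model.factors[f]}~~{self.model.factors[g]}",
                         "kind": "factor_corr", "est": self.theta[nl + e],
                         "se": self.bse[nl + e]})
        base = nl + len(gs._phi_idx)
        for t in range(self.model.k):
            rows.append({"param": f"{self.model.traits[t]}~~{self.model.traits[t]}",
                         "kind": "residual", "est": self.theta[base + t],
                         "se": self.bse[base + t]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = (f"Genomic SEM (DWLS), {self.model.k} traits, {self.model.q} factors\n"
                f"chi2({self.df}) = {self.chi2:.3f}, p = {self.pvalue:.3g}, "
                f"AIC = {self.aic:.3f}, CFI = {self.cfi:.3f}, SRMR = {self.srmr:.4f}\n"
                f"converged: {self.converged} (|grad| = {self.grad_norm:.2e})\n")
        return head + self.param_table().to_string(index=False, float_format="%.4f")

    # ------------------------------------------------------------------
    def snp_edges(self, hset: HarmonizedSet, factor, residual_traits,
                  maf: np.ndarray | None = None,
                  account_loading_uncertainty: bool = True) -> "SNPEdgeResult":
        """Per-SNP direct paths with the measurement model held fixed.

        Parameters
        ----------
        hset : harmonized sumstats whose trait order matches the model.
        factor : factor label or index receiving a SNP->factor path.
        residual_traits : trait labels/indices receiving SNP->residual paths.
        account_loading_uncertainty : propagate the sampling covariance of
            the fixed loadings into the path variances (delta method).
            Holding a noisily estimated measurement model fixed otherwise
            leaves the residual paths anti-conservative, because loading
            error times the SNP's factor signal leaks into them.

        Returns one effect/SE/Z/p set per path per SNP (closed-form weighted
        least squares; the SNP variance ``2p(1-p)`` cancels).
        """
        if hset.k != self.model.k:
            raise ValueError("harmonized set / model dimension mismatch")
        f_idx = (self.model.factors.index(factor) if isinstance(factor, str) else int(factor))
        r_idx = [self.model.traits.index(t) if isinstance(t, str) else int(t)
                 for t in residual_traits]
        k = self.model.k
        npaths = 1 + len(r_idx)
        X = np.zeros((k, npaths))
        X[:, 0] = self.Lambda[:, f_idx]
        for c, t in enumerate(r_idx):
            X[t, 1 + c] = 1.0

        B = hset.betas()
        SE = hset.ses()
        valid = np.all(np.isfinite(B), axis=1) & np.all(SE > 0, axis=1)
        n_skipped = int((~valid).sum())
        w = np.zeros_like(SE)
        w[valid] = 1.0 / SE[valid] ** 2
        # batched (X' W_j X) and (X' W_j y_j)
        A = np.einsum("tk,jt,tl->jkl", X, w, X)
        c = np.einsum("tk,jt,jt->jk", X, w, B)
        m = B.shape[0]
        est = np.full((m, npaths), np.nan)
        se = np.full((m, npaths), np.nan)
        ok = valid.copy()
        Av = A[valid]
        try:
            Ainv = np.linalg.inv(Av)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(Av)
        est[valid] = np.einsum("jkl,jl->jk", Ainv, c[valid])
        var = np.einsum("jkk->jk", Ainv).copy()

        if account_loading_uncertainty and hasattr(self, "param_cov"):
            var += self._loading_uncertainty_var(
                f_idx, r_idx, X, w[valid], B[valid], est[valid], valid, npaths)
        se[valid] = np.sqrt(np.maximum(var, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = est / se
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        p = np.where(np.isfinite(z), p, np.nan)

        if maf is None:
            maf = hset.members[0].table["MAF"].to_numpy(float)
        maf = np.minimum(maf, 1 - maf)
        path_names = ([f"factor:{self.model.factors[f_idx]}"]
                      + [f"residual:{self.model.traits[t]}" for t in r_idx])
        # per-path effective N averaged over well-behaved-MAF SNPs
        band = ok & (maf >= 0.10) & (maf <= 0.40)
        eff_n = {}
        for c_, name in enumerate(path_names):
            with np.errstate(divide="ignore", invalid="ignore"):
                nhat = 1.0 / (se[:, c_] ** 2 * 2.0 * maf * (1.0 - maf))
            eff_n[name] = float(np.nanmean(nhat[band])) if band.any() else float("nan")
        if n_skipped:
            logger.info("snp_edges: skipped %d SNPs with missing effects", n_skipped)
        return SNPEdgeResult(path_names=path_names, est=est, se=se, z=z, p=p,
                             valid=ok, eff_n=eff_n, hset=hset, n_skipped=n_skipped)


    def _loading_uncertainty_var(self, f_idx, r_idx, X, w_v, B_v, est_v,
                                 valid, npaths) -> np.ndarray:
        """Delta-method variance contribution of the fixed-but-estimated
        loadings, per SNP and path (rows = valid SNPs)."""
        gs = self.model_obj
        k = self.model.k
        # covariance of the factor-f loading estimates, embedded k x k
        C = np.zeros((k, k))
        load_params = [(c, t) for c, (t, f) in enumerate(gs._load_idx) if f == f_idx]
        for c1, t1 in load_params:
            for c2, t2 in load_params:
                C[t1, t2] = self.param_cov[c1, c2]
        lam = self.Lambda[:, f_idx]
        in_u = np.ones(k, dtype=bool)
        in_u[r_idx] = False
        bhat = est_v[:, 0]
        den = (w_v[:, in_u] * lam[in_u] ** 2).sum(axis=1)
        den = np.where(den > 0, den, np.inf)
        db = np.zeros_like(w_v)
        db[:, in_u] = (w_v[:, in_u] * (B_v[:, in_u] - 2.0 * lam[in_u] * bhat[:, None])
                       / den[:, None])
        out = np.zeros((w_v.shape[0], npaths))
        q = np.einsum("jk,kl,jl->j", db, C, db)
        out[:, 0] = q
        for c, t in enumerate(r_idx):
            r_t = db @ C[:, t]
            out[:, 1 + c] = lam[t] ** 2 * q + bhat ** 2 * C[t, t] + 2 * lam[t] * bhat * r_t
        return np.maximum(out, 0.0)


@dataclass
class SNPEdgeResult:
    """Per-SNP effects for each direct path of the SNP-edge model."""

    path_names: list
    est: np.ndarray       # (m, npaths)
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    valid: np.ndarray
    eff_n: dict
    hset: HarmonizedSet
    n_skipped: int = 0

    def path_index(self, name: str) -> int:
        matches = [i for i, n in enumerate(self.path_names) if name in n]
        if len(matches) != 1:
            raise KeyError(f"path {name!r} not found uniquely in {self.path_names}")
        return matches[0]

    def mean_chisq(self, path, snp_mask=None) -> float:
        c = self.path_index(path) if isinstance(path, str) else path
        zz = self.z[:, c] ** 2
        if snp_mask is not None:
            zz = zz[snp_mask]
        return float(np.nanmean(zz))

    def n_genome_wide_significant(self, path) -> int:
        c = self.path_index(path) if isinstance(path, str) else path
        return int(np.nansum(self.p[:, c] < GENOME_WIDE_SIG))

    def to_sumstats(self, path) -> SumStats:
        """Emit one path's effects in the canonical SumStats dialect so the
        PGS stage consumes them identically to traditional GWAS."""
        c = self.path_index(path) if isinstance(path, str) else path
        ref = self.hset.members[0].table
        table = pd.DataFrame({
            "SNP": ref["SNP"], "CHR": ref["CHR"], "BP": ref["BP"],
            "A1": ref["A1"], "A2": ref["A2"],
            "BETA": self.est[:, c], "SE": self.se[:, c], "P": self.p[:, c],
            "N": self.eff_n[self.path_names[c]], "MAF": ref["MAF"],
        })
        table = table[self.valid].reset_index(drop=True)
        return SumStats(table, trait=self.path_names[c],
                        meta={"effective_n": self.eff_n[self.path_names[c]],
                              "source": "snp_edge"})


# ======================================================================
def fit_cfa_dwls(model: SEMModel, cov: CovStructure, **fit_kwargs) -> GenomicSEMResults:
    """Convenience wrapper: ``GenomicSEM(cov, model).fit(...)``."""
    return GenomicSEM(cov, model).fit(**fit_kwargs)


def compare_cfa_models(fits: list, labels: list | None = None) -> pd.DataFrame:
    """Rank fitted CFA models by AIC; reports all indices per model."""
    if not fits:
        raise ValueError("no fitted models")
    rows = []
    for i, fit in enumerate(fits):
        rows.append({
            "model": labels[i] if labels else f"{fit.model.q}-factor",
            "n_factors": fit.model.q, "n_free": fit.n_free,
            "chi2": fit.chi2, "df": fit.df, "AIC": fit.aic,
            "CFI": fit.cfi, "SRMR": fit.srmr,
        })
    return (pd.DataFrame(rows).sort_values("AIC", kind="mergesort")
            .reset_index(drop=True))
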