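"""Covariate-adjusted PGS association tests, FDR, and the discrimination /
genetic-correlation-attenuation reports.

Each outcome is regressed on one standardized score plus covariates
(biological sex, age, 10 genetic principal components by convention);
binary outcomes use logistic regression with Nagelkerke pseudo-r^2 for the
incremental variance explained, continuous/count outcomes use linear
regression with ordinary r^2.  P-values are Benjamini-Hochberg adjusted
within the declared family (all outcomes for one score in one sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .ldsc import LDScores, fit_ldsc_pair  # noqa: F401  (LDScores is part of the API surface)

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult", "DiscriminationReport", "ModelFitError",
    "fit_association", "bh_adjust", "association_table",
    "discrimination_report", "rg_attenuation_table",
]


class ModelFitError(RuntimeError):
    """Raised when an outcome cannot support the regression (e.g. prevalence
    below the 1% floor)."""


@dataclass
class AssocResult:
    outcome: str
    score: str
    B: float                 # unstandardized coefficient per SD of PGS
    se: float
    p: float
    incremental_r2: float
    family: str              # "linear" | "logistic"
    n: int
    p_fdr: float = float("nan")
    r2_clamped: bool = False

    def as_row(self) -> dict:
        return {"outcome": self.outcome, "score": self.score, "B": self.B,
                "se": self.se, "p": self.p, "p_fdr": self.p_fdr,
                "r2": self.incremental_r2, "family": self.family, "n": self.n}


def _nagelkerke(loglik_full: float, loglik_null: float, n: int) -> float:
    cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    return cs / denom if denom > 0 else float("nan")


def fit_association(outcome: np.ndarray, score: np.ndarray,
                    covariates: pd.DataFrame | np.ndarray | None = None,
                    outcome_label: str = "outcome", score_label: str = "score",
                    family: str | None = None, r2_method: str = "nagelkerke",
                    prevalence_floor: float = 0.01,
                    min_complete: int = 50) -> AssocResult:
    """Test one score against one outcome with covariate adjustment.

    The incremental r^2 is ``r2(covariates + PGS) - r2(covariates)``
    (ordinary r^2 for linear models, Nagelkerke -- or McFadden via
    ``r2_method`` -- pseudo-r^2 for logistic), clamped at 0 and flagged when
    negative before clamping.
    """
    y = np.asarray(outcome, float).ravel()
    s = np.asarray(score, float).ravel()
    if covariates is None:
        C = np.empty((len(y), 0))
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
    complete = np.isfinite(y) & np.isfinite(s) & np.all(np.isfinite(C), axis=1)
    y, s, C = y[complete], s[complete], C[complete]
    n = len(y)
    if n < min_complete:
        raise ModelFitError(f"{outcome_label}: only {n} complete cases (< {min_complete})")

    if family is None:
        family = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    Xc = sm.add_constant(C, has_constant="add")
    Xf = np.column_stack([Xc, s])

    if family == "logistic":
        prev = min(y.mean(), 1 - y.mean())
        if prev < prevalence_floor:
            raise ModelFitError(
                f"{outcome_label}: model fitting error (prevalence {prev:.3%} "
                f"below {prevalence_floor:.0%} floor)")
        null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
        red = sm.Logit(y, Xc).fit(disp=0)
        full = sm.Logit(y, Xf).fit(disp=0)
        if r2_method == "nagelkerke":
            r2_full = _nagelkerke(full.llf, null.llf, n)
            r2_red = _nagelkerke(red.llf, null.llf, n)
        elif r2_method == "mcfadden":
            r2_full = 1.0 - full.llf / null.llf
            r2_red = 1.0 - red.llf / null.llf
        else:
            raise ValueError(f"unknown r2_method {r2_method!r}")
    else:
        red = sm.OLS(y, Xc).fit()
        full = sm.OLS(y, Xf).fit()
        r2_full, r2_red = full.rsquared, red.rsquared

    inc = r2_full - r2_red
    clamped = inc < 0
    if clamped:
        logger.info("fit_association[%s~%s]: negative incremental r2 clamped to 0",
                    outcome_label, score_label)
    return AssocResult(outcome=outcome_label, score=score_label,
                       B=float(full.params[-1]), se=float(full.bse[-1]),
                       p=float(full.pvalues[-1]),
                       incremental_r2=float(max(inc, 0.0)),
                       family="logistic" if family == "logistic" else "linear",
                       n=n, r2_clamped=bool(clamped))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def association_table(results: list) -> pd.DataFrame:
    """Apply BH within each score family and assemble the report table."""
    df = pd.DataFrame([r.as_row() for r in results])
    for score, idx in df.groupby("score").groups.items():
        adj = bh_adjust(df.loc[idx, "p"].to_numpy())
        df.loc[idx, "p_fdr"] = adj
        for r, a in zip(np.asarray(results, dtype=object)[np.asarray(idx)], adj):
            r.p_fdr = float(a)
    return df


@dataclass
class DiscriminationReport:
    """Significant-association counts over non-focal outcomes for a pair of
    scores tested on identical outcome sets, plus per-outcome delta r^2."""

    score_a: str
    score_b: str
    focal_outcomes: list
    alpha: float
    n_nonfocal: int
    sig_count: dict               # score -> count of significant non-focal hits
    sig_outcomes: dict            # score -> list of outcome labels
    focal_rows: pd.DataFrame
    delta_r2: pd.DataFrame        # per outcome: r2_a - r2_b

    def summary(self) -> str:
        lines = [f"Discrimination report ({self.score_a} vs {self.score_b}), "
                 f"alpha = {self.alpha} on FDR-adjusted p:"]
        for s, c in self.sig_count.items():
            hits = ", ".join(self.sig_outcomes[s]) or "none"
            lines.append(f"  {s}: {c} / {self.n_nonfocal} non-focal outcomes ({hits})")
        return "\n".join(lines)


def discrimination_report(table: pd.DataFrame, score_a: str, score_b: str,
                          focal_outcomes, alpha: float = 0.05) -> DiscriminationReport:
    """Compare two scores' non-focal association footprints.

    ``table`` is an :func:`association_table` output containing both scores
    tested on identical outcome sets; significance is ``p_fdr < alpha``.
    """
    ta = table[table["score"] == score_a]
    tb = table[table["score"] == score_b]
    outs_a, outs_b = set(ta["outcome"]), set(tb["outcome"])
    if outs_a != outs_b:
        raise ValueError(f"outcome sets differ: {sorted(outs_a ^ outs_b)}")
    focal = list(focal_outcomes)
    nonfocal = sorted(outs_a - set(focal))
    sig_count, sig_outcomes = {}, {}
    for s, t in ((score_a, ta), (score_b, tb)):
        nf = t[t["outcome"].isin(nonfocal)]
        hits = nf.loc[nf["p_fdr"] < alpha, "outcome"].tolist()
        sig_count[s] = len(hits)
        sig_outcomes[s] = sorted(hits)
    merged = ta.merge(tb, on="outcome", suffixes=("_a", "_b"))
    delta = pd.DataFrame({"outcome": merged["outcome"],
                          "delta_r2": merged["r2_a"] - merged["r2_b"]})
    focal_rows = table[table["outcome"].isin(focal)
                       & table["score"].isin([score_a, score_b])].copy()
    return DiscriminationReport(score_a=score_a, score_b=score_b,
                                focal_outcomes=focal, alpha=alpha,
                                n_nonfocal=len(nonfocal), sig_count=sig_count,
                                sig_outcomes=sig_outcomes, focal_rows=focal_rows,
                                delta_r2=delta)


def rg_attenuation_table(traditional: dict, residual: dict, external: dict,
                         ld: LDScores, n_blocks: int = 200) -> pd.DataFrame:
    """Bivariate-LDSC genetic correlations of traditional vs residual
    (disorder-specific) sumstats with a set of external traits.

    All inputs are ``{label: SumStats}`` on the LD-score SNP universe.
    Returns one row per (focal trait, external trait) with rg +/- SE for both
    sources and the paired attenuation ``|rg_traditional| - |rg_residual|``.
    Pair-level LDSC failures are recorded as NaN rows, not fatal.
    """
    rows = []
    for focal in traditional:
        if focal not in residual:
            raise ValueError(f"no residual sumstats for focal trait {focal!r}")
        for ext_label, ext_ss in external.items():
            row = {"focal": focal, "external": ext_label}
            for tag, ss in (("traditional", traditional[focal]),
                            ("residual", residual[focal])):
                try:
                    own = fit_ldsc_pair(ss, ss, ld, n_blocks=n_blocks)
                    ex = fit_ldsc_pair(ext_ss, ext_ss, ld, n_blocks=n_blocks)
                    cross = fit_ldsc_pair(ss, ext_ss, ld, n_blocks=n_blocks)
                    denom = np.sqrt(max(own.slope, 1e-12) * max(ex.slope, 1e-12))
                    row[f"rg_{tag}"] = cross.slope / denom
                    row[f"rg_{tag}_se"] = cross.slope_se / denom
                except Exception as err:
                    logger.warning("rg_attenuation: pair (%s, %s, %s) failed: %s",
                                   focal, ext_label, tag, err)
                    row[f"rg_{tag}"] = row[f"rg_{tag}_se"] = float("nan")
            row["attenuation"] = abs(row["rg_traditional"]) - abs(row["rg_residual"])
            rows.append(row)
    return pd.DataFrame(rows)
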