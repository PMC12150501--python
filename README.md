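# pgsem

Disorder-specific polygenic scores via genomic structural equation modeling.

Polygenic scores (PGS) for psychiatric disorders predict their focal outcome
but also, through pervasive genetic overlap, almost everything comorbid with
it — an ADHD score predicts depression, autism and conduct problems, which
ruins its value as a *discriminating* instrument.  `pgsem` implements the
pipeline that sharpens a disorder's PGS by removing the shared genetic
signal: it estimates the genetic covariance matrix among k disorders from
GWAS summary statistics by multivariable LD score regression, models it with
a confirmatory factor model (genomic SEM), adds per-SNP "edge" paths that
split each SNP's effect into a latent-factor component and disorder-specific
residuals, and builds clumping + thresholding scores from the residual
summary statistics, with the p-value threshold tuned by summary-statistic
cross-validation and associations tested with covariates and FDR control.
A synthetic multi-trait GWAS generator makes every stage verifiable by
parameter recovery, with no external downloads.

The core model: per-SNP z-score products obey

    E[z1j z2j] = sqrt(N1 N2) * rho_g * l_j / M + intercept

with `l_j` the LD score, giving the genetic covariance matrix **S** and its
block-jackknife sampling covariance **V**.  The measurement model
`Sigma(theta) = Lambda Phi Lambda' + Theta` is fitted to **S** by diagonally
weighted least squares, `F = (s - sigma)' diag(V)^{-1} (s - sigma)`, with
sandwich standard errors, chi-square/AIC/CFI/SRMR fit indices, and per-SNP
direct paths estimated with the measurement model fixed.  See
`docs/methods.md` for the full account.

It is intended for statistical geneticists and psychiatric-genetics
researchers who have GWAS summary statistics for a set of correlated
disorders and want scores that distinguish them.

## Worked example

A four-trait study in which "ADHD" and "ASD" share one latent factor; the
goal is an ADHD score that does *not* predict ASD.

```python
import numpy as np
from pgsem import *
from pgsem.gsem import GenomicSEM, SEMModel
from pgsem.studies import default_panel

panel = default_panel(m=2000, seed=7)
Lam = np.array([[0.75], [0.75], [0.80], [0.70]])
arch = TrueArchitecture(Lambda=Lam, Psi=1 - (Lam @ Lam.T).diagonal(),
                        h2=np.full(4, 0.4), specific_causal_fraction=0.1,
                        trait_labels=["ADHD", "ASD", "C", "D"])
specs = [CohortSpec(trait=t, n=20000, label=l)
         for t, l in enumerate(["ADHD", "ASD", "C", "D"])]
suite = make_gwas_suite(panel, arch, specs, seed=7)

ld = compute_ld_scores(panel=panel, window_kb=1000)
hset = harmonize(suite.sumstats)
cov = build_cov_structure(hset, ld, n_blocks=80, chisq_cap=False)
rg, se = genetic_correlation(cov, 0, 1)
print(f"rg(ADHD, ASD) = {rg:.3f} +/- {se:.3f}")

fit = GenomicSEM(cov, SEMModel.unidimensional(cov.traits)).fit()
print(fit.summary())

edges = fit.snp_edges(hset, factor=0, residual_traits=["ADHD", "ASD"])
resid_adhd = edges.to_sumstats("residual:ADHD")

clumped = clump(resid_adhd, panel, window_kb=1000, r2_max=0.1)
cv = cv_select_threshold(clumped, folds=4, seed=7)
print(f"{len(clumped)} index SNPs; selected p-value threshold: {cv.selected:g}")

G_t, pheno = simulate_target_cohort(panel, suite.truth, 5000, seed=7)
w = PGSWeights.from_sumstats(clumped, threshold=cv.selected)
scores = compute_pgs(w, G_t, panel.snp_ids, np.repeat("A", panel.m),
                     np.repeat("G", panel.m))
covs = pheno[["sex", "age"] + [f"PC{i}" for i in range(1, 11)]]
for outcome in ("trait0", "trait1"):
    res = fit_association(pheno[outcome].to_numpy(), scores["score"].to_numpy(),
                          covs, outcome_label=outcome,
                          score_label="ADHD-specific PGS")
    print(f"{outcome}: B = {res.B:.3f} (se {res.se:.3f}), p = {res.p:.2g}, "
          f"incremental r2 = {res.incremental_r2:.4f}")
```

Output (about 30 s):

```
rg(ADHD, ASD) = 0.534 +/- 0.109
Genomic SEM (DWLS), 4 traits, 1 factors
chi2(2) = 0.866, p = 0.649, AIC = 16.866, CFI = 1.000, SRMR = 0.0133
converged: True (|grad| = 3.66e-08)
     param     kind    est     se
   ADHD~F1  loading 0.4543 0.0743
    ASD~F1  loading 0.5059 0.0650
      C~F1  loading 0.5564 0.0763
      D~F1  loading 0.4848 0.0738
ADHD~~ADHD residual 0.1542 0.0826
  ASD~~ASD residual 0.2156 0.0757
      C~~C residual 0.1534 0.0622
      D~~D residual 0.1669 0.0677
1119 index SNPs; selected p-value threshold: 1
trait0: B = 0.330 (se 0.026), p = 2.4e-36, incremental r2 = 0.0312
trait1: B = 0.021 (se 0.027), p = 0.43, incremental r2 = 0.0001
```

Reading it: the two focal traits are genetically correlated (rg 0.53)
through the shared factor, yet the ADHD-specific score built from the
residual-path scan explains 3.1% of variance in the ADHD outcome
(`trait0`) and essentially nothing (0.01%, p = 0.43) in the ASD outcome
(`trait1`) — the discriminatory behaviour the residualization is for.
A traditional ADHD score on the same data carries its factor component into
the ASD outcome (incremental r² ≈ 0.02; see `pgsem.studies.attenuation_run`).

A thin CLI mirrors the stages (`pgsem simulate | munge | ldsc | gsem | pgs |
assoc`); run `pgsem --help`.

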