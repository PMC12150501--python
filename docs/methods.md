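# Methods

`pgsem` implements the pipeline that turns a set of GWAS summary statistics
for genetically correlated disorders into *disorder-specific* polygenic
scores: multivariable LD score regression builds the genetic covariance
structure, a genomic structural equation model separates shared (latent
factor) from trait-specific genetic signal via per-SNP "edge" paths, and the
resulting residual summary statistics feed a standard clumping + p-value
thresholding score whose threshold is tuned by summary-statistic
cross-validation.  This note records the models, the numerical choices, and
what the synthetic experiments do and do not establish.

## Synthetic data generator

The generator is first-class code: every downstream stage is validated by
recovering the generating values.

**LD panel.** A single pseudo-chromosome of `m` SNPs in blocks, 1-based
positions at a fixed 5 kb spacing (so the conventional 1000 kb clumping
window spans 200 SNPs).  Within a block of correlation parameter `rho` the
true LD matrix is AR(1), `R_ij = rho^|i-j|`; across blocks it is zero.

**Genotypes.** Two independent haplotypes per individual; within a block a
haplotype is a stationary two-state Markov chain with marginal frequency
`maf` and adjacent correlation `rho`.  Because the lag-k correlation of a
two-state chain is the product of the adjacent correlations, the genotype
correlation matrix equals `R` *exactly*, allele frequencies are exact, and
Hardy-Weinberg holds by construction.  (A thresholded-Gaussian copula was
considered and rejected: thresholding attenuates the latent correlation --
a target r of 0.5 realizes near 0.33 at maf 0.25 -- which breaks LD score
calibration and the convergence of empirical LD to `R`.)  Fréchet bounds
cap the correlation attainable between binary variables of different
frequencies, so MAF is drawn uniformly per *block* and is constant within
it; real LD blocks likewise share genealogy and allele-frequency history.

**Trait architecture.** On the standardized genetic scale, trait `t`'s
genetic value is `sqrt(h2_t) * (Lambda_t . F + s_t)` with unit-variance
factors `F` (correlation `Phi`) and specific components `s_t` of variance
`Psi_t`, subject to `diag(Lambda Phi Lambda') + Psi = 1`.  Per-SNP effects
are Gaussian on standardized dosages, restricted to causal sets given either
as fractions or as explicit masks; factor scores and specific components are
rescaled to their exact target variances in the simulated population, so
realized heritability matches `h2` up to the environmental draw.
Case-control traits threshold the liability at the stated prevalence.

**Cohorts.** One population is simulated; cohorts are index sets into it, so
overlapping cohorts share genotypes *and* environment.  For a same-trait
pair sharing `Ns` of `N` individuals the expected cross-trait LDSC intercept
is `Ns * r / sqrt(N1 N2)` with `r` the phenotypic correlation among the
shared individuals; the generator records this expectation.  GWAS scans are
least squares for quantitative traits and one-step score-based logistic
regression for binary traits, with two-sided normal p-values (so `|z|` and
`P` are exactly consistent).

**What the generator does not emulate.** Realistic recombination maps and
LD decay, imputation uncertainty, allele-frequency-dependent architectures,
ancestry structure/admixture, X chromosome, genotyping error.  Passing
parameter-recovery tests here shows the estimators are correct under their
own assumptions, not that those assumptions hold in any real cohort.

## LD score regression

LD scores are `l_j = sum_k r^2_jk` over a window (default 1000 kb), from the
panel's true `R` (block-wise, never densified) or from reference dosages
with the small-sample adjustment `r2 - (1 - r2)/(n - 2)`.  The regression is

    E[z1_j z2_j] = sqrt(N1 N2) * rho_g * l_j / M + intercept,

(univariate: chi2 on `N l / M`, intercept expected 1), fitted by weighted
least squares with the standard heteroskedasticity weights
`1 / (l_j * var_j)` where `var_j` uses the current expected values;
two reweighting passes.  Intercepts are always free, absorbing overlap and
confounding.

**Chi-square cap.** The conventional outlier cap `chi2 > max(80, 0.001 N)`
is the default but is disabled in the desk-scale suites: with `m = 2000`
SNPs carrying the full heritability, per-SNP noncentralities of genuine
polygenic signal routinely exceed 80, and capping then truncates true
signal (measured bias: h2 0.24 instead of 0.30).  The cap is an artifact
filter scaled to genome-wide SNP counts, not a property of the estimand.

**Block jackknife.** `S`'s sampling covariance `V` comes from delete-one
pseudovalues over contiguous SNP blocks shared across all trait pairs
(default 200 blocks, the field convention).  Two desk-scale caveats, both
verified empirically and reflected in the canonical studies:

* jackknife blocks must be at least as long as an LD block, otherwise
  adjacent blocks are correlated and `V` is underestimated (observed 15%
  SE deficit with 10-SNP jackknife blocks inside 25-SNP LD blocks); the
  m = 2000 studies use 80 jackknife blocks aligned to LD-block boundaries,
  which are exactly independent;
* when the number of unique `S` elements `k(k+1)/2` approaches the number
  of blocks, the sample covariance is ill-conditioned and the model
  chi-square (which uses `V^{-1}`) explodes along the distorted small
  eigenvalues.  `build_cov_structure(..., shrink_v=True)` applies
  Ledoit-Wolf shrinkage to the *correlation* structure of the pseudovalues
  only, preserving the marginal sampling variances (element-wise SEs are
  untouched).  The 9-trait study (45 elements, 80 blocks) uses it; the
  4-trait study (10 elements) does not need it.

The intercept-recovery study runs at `m = 20000, n = 2000`: intercept
precision scales with the per-SNP chi-square variance, so a realistic N/M
ratio is needed for the check to have any resolution.

## Genomic SEM

**Input.** `S` is projected to positive definiteness by eigenvalue clipping
at 1e-6 on the correlation scale, rescaled to the original variances; `V` is
passed through unchanged (element-wise rescaling of sampling variances is
ill-defined when smoothing flips or zeroes an element) with the diagnostic
`max |S - S'|` reported.

**EFA.** Principal-axis extraction (statsmodels) on the correlation-scaled
`S`, then promax rotation.  Varimax/promax are implemented in
`pgsem.rotation` because the reference implementations (statsmodels, and R's
`stats::promax`, checked directly) stall at a 45-degree saddle of the
varimax criterion on near-symmetric simple structures; the implementation
runs the SVD iteration from several deterministic random starts and keeps
the best criterion value.  Eigenvalue retention (> 1) is reported alongside.

**CFA.** `Sigma(theta) = Lambda Phi Lambda' + Theta` with unit factor
variances (so SNP->factor paths share a scale), free factor correlations
(bounded +-0.999) and residual variances bounded at zero.  The DWLS
objective `(s - sigma)' diag(V)^{-1} (s - sigma)` is minimized as a
weighted least-squares problem by trust-region reflective Gauss-Newton with
the analytic Jacobian, from multiple starts; at an exact-fit input the
solution is recovered to machine precision.  Standard errors are sandwich
estimates using the full `V`.  The model chi-square is the V-weighted
residual quadratic form `r' pinv(V) r` with `df = k(k+1)/2 - n_free`;
AIC = chi2 + 2 n_free; CFI uses an independence model (free diagonal, zero
covariances) fitted under the same weights; SRMR is computed on the
correlation scale.  CFA patterns come from the EFA loadings (free where
|loading| > 0.30, orphan traits assigned to their best factor, empty
factors dropped) or from an explicit loading map.

**SNP edges.** With the measurement model held at its estimate, the
covariance matrix is augmented per SNP with
`cov(SNP, trait_t) = beta_t * 2p(1-p)` and refit with free paths
SNP->factor and SNP->residual for the designated traits.  Because the
measurement part is fixed, the refit is a linear weighted least squares in
which the SNP variance cancels; all SNPs are solved in one batched
closed form.  Holding estimated loadings fixed leaves the residual paths
anti-conservative -- loading error times the SNP's factor signal leaks into
them -- so the loading sampling covariance is propagated into the per-SNP
path variances by the delta method (default on; this restored null mean
chi-square from ~1.09 to ~0.98 in the calibration study).  Effective N per
output is `1 / (se^2 * 2p(1-p))` averaged over SNPs with MAF in
[0.10, 0.40], recorded in the output metadata; outputs are written in the
same sumstats dialect as any GWAS so the scoring stage is source-agnostic.

## Polygenic scores

Greedy clumping (smallest p first, claim neighbours within 1000 kb with
r^2 > 0.1; ties on p broken by chromosome and position so output is
row-order invariant), then p-value thresholding over
{1, 0.1, 0.01, 0.001, 1e-4, 5e-8}.  The threshold is selected by
summary-statistic subsampling: on the standardized scale
`r_hat = z / sqrt(N)`, a training replicate `r_tr ~ N(r_hat, 1/N_tr - 1/N)`
and the complementary test statistic `r_te = (N r_hat - N_tr r_tr)/N_te`
satisfy `N_tr r_tr + N_te r_te = N r_hat` exactly; predictive
`r^2 = (sum w r_te)^2 / sum w^2` assumes independence after clumping (a
recorded approximation), averaged over 4 folds at a 75/25 split, argmax
selected.  Scoring aligns each weight's effect allele against the genotype
coding (flipping dosage `2 - d` where needed), mean-imputes missing
dosages, and z-standardizes the scores.

## Association testing

Each outcome is regressed on one standardized score plus covariates (sex,
age, 10 PCs by convention); binary outcomes use logistic regression with a
1% prevalence floor and Nagelkerke pseudo-r^2 (McFadden available),
continuous/count outcomes use linear regression with ordinary r^2.
Incremental r^2 is the covariates+score minus covariates-only difference,
clamped at zero with a flag.  BH-FDR is applied within the family of all
outcomes for one score in one sample.  The discrimination report counts
FDR-significant non-focal associations per score and tabulates per-outcome
delta r^2; the rg-attenuation table runs bivariate LDSC for every
(source, external trait) pair.

## Canonical studies and their sizes

All fixed in `pgsem.studies`, shared by the test suite and
`scripts/acceptance.py`: m = 2000 SNPs in 80 AR(1) blocks of 25 with
correlations cycling (0, 0.3, 0.5, 0.7, 0.85) -- LD scores then span 1 to
~6, which gives the LD score regression its leverage; GWAS cohorts of
n = 20000; target samples of n = 5000; 10 seeds for the stochastic claims.
The SNP-edge calibration study confines each trait's specific effects to
its own 8 LD blocks so that factor-only blocks are exact nulls and the
marginal specific effect is the LD-convolution of the generating one; the
attenuation study instead scatters sparse (10%) specifics genome-wide so
that the residual outputs' signal is proportional to LD score and their
LDSC heritability denominators are stable.  The threshold-regime studies
use a single trait with either fully polygenic weak effects (h2 = 0.2,
n = 5000) or 1% causal large effects (h2 = 0.5, n = 20000).

## Known limitations

* Case-control GWAS are on the observed (0/1) scale via a one-step score
  approximation; liability-scale conversion is out of scope.
* The subsampling r^2 evaluator ignores residual LD among clumped SNPs.
* `V` is passed through PD smoothing unchanged; with heavy smoothing the
  sandwich SEs are approximate.
* Cross-trait LDSC weights use the additive "+1" sampling term, so exact
  scale-invariance of rg holds only in the univariate limit.
* The SNP-edge model fixes the measurement model per the usual practice;
  the delta-method variance correction assumes loading errors are small
  relative to the loadings themselves.
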