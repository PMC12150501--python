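"""Generator correctness: LD structure, genotype moments, phenotype
architecture, GWAS calibration, cohort overlap."""

import numpy as np
import pytest
from scipy import stats

from pgsem.simulate import (CohortSpec, TrueArchitecture,
                            expected_genotype_correlation, make_gwas_suite,
                            run_gwas, simulate_genotypes, simulate_ld_panel,
                            simulate_multitrait_phenotypes,
                            simulate_target_cohort)


class TestLDPanel:
    def test_single_snp_block_is_identity(self):
        panel = simulate_ld_panel(block_sizes=[1], rhos=[0.5], seed=0)
        assert panel.R == pytest.approx(np.array([[1.0]]))

    def test_ar1_closed_form(self):
        panel = simulate_ld_panel(block_sizes=[3], rhos=[0.5], seed=0)
        off = panel.R[np.triu_indices(3, 1)]
        assert off == pytest.approx([0.5, 0.25, 0.5])

    def test_cross_block_independence(self):
        panel = simulate_ld_panel(block_sizes=[2, 2], rhos=[0.9, 0.0], seed=0)
        assert np.all(panel.R[:2, 2:] == 0)

    def test_r_is_psd_with_unit_diagonal(self, tiny_panel):
        w = np.linalg.eigvalsh(tiny_panel.R)
        assert w.min() > -1e-10
        assert np.diag(tiny_panel.R) == pytest.approx(1.0)
        assert np.all(np.diff(tiny_panel.positions) > 0)

    @pytest.mark.parametrize("bad_rho", [1.0, 1.5, -0.1])
    def test_invalid_rho_rejected(self, bad_rho):
        with pytest.raises(ValueError):
            simulate_ld_panel(block_sizes=[5], rhos=[bad_rho], seed=0)

    def test_block_size_sum_must_match_m(self):
        with pytest.raises(ValueError, match="sum of block sizes"):
            simulate_ld_panel(block_sizes=[5, 5], rhos=0.2, m=11, seed=0)


class TestGenotypes:
    def test_single_individual_shape_and_range(self, tiny_panel):
        G = simulate_genotypes(tiny_panel, 1, seed=0)
        assert G.shape == (1, tiny_panel.m)
        assert set(np.unique(G)) <= {0, 1, 2}

    def test_determinism(self, tiny_panel):
        a = simulate_genotypes(tiny_panel, 100, seed=5)
        b = simulate_genotypes(tiny_panel, 100, seed=5)
        assert np.array_equal(a, b)
        c = simulate_genotypes(tiny_panel, 100, seed=6)
        assert not np.array_equal(a, c)

    def test_allele_frequency_and_ld_converge(self):
        panel = simulate_ld_panel(block_sizes=[10] * 10,
                                  rhos=[0.0, 0.2, 0.4, 0.6, 0.8] * 2,
                                  m=100, seed=3)
        G = simulate_genotypes(panel, 50000, seed=3)
        freq = G.mean(axis=0) / 2.0
        assert np.abs(freq - panel.maf).max() < 0.01
        emp = np.corrcoef(G.astype(float).T)
        assert np.abs(emp - panel.R).max() < 0.05

    def test_pair_correlation_matches_closed_form(self):
        panel = simulate_ld_panel(block_sizes=[2], rhos=[0.8], seed=1)
        G = simulate_genotypes(panel, 50000, seed=1)
        emp = np.corrcoef(G[:, 0].astype(float), G[:, 1].astype(float))[0, 1]
        assert emp == pytest.approx(expected_genotype_correlation(panel, 0, 1),
                                    abs=0.03)

    def test_hardy_weinberg(self):
        panel = simulate_ld_panel(block_sizes=[1], rhos=[0.0],
                                  maf_range=(0.3, 0.3), seed=2)
        G = simulate_genotypes(panel, 50000, seed=2)
        counts = np.bincount(G[:, 0], minlength=3) / 50000
        f = panel.maf[0]
        assert counts == pytest.approx([(1 - f) ** 2, 2 * f * (1 - f), f ** 2],
                                       abs=0.01)


def _one_factor_arch(lam, h2, **kw):
    lam = np.atleast_2d(np.asarray(lam, float)).T if np.ndim(lam) == 1 else lam
    Psi = 1.0 - (lam @ lam.T).diagonal()
    return TrueArchitecture(Lambda=lam, Psi=Psi, h2=np.asarray(h2, float), **kw)


class TestPhenotypes:
    def test_generating_rg_from_loadings(self):
        # Lambda = (0.7, 0.7), Psi = 0.51: rg = 0.7 * 0.7 = 0.49
        arch = _one_factor_arch(np.array([0.7, 0.7]), [0.5, 0.5])
        assert arch.genetic_correlation()[0, 1] == pytest.approx(0.49)

    def test_unit_loadings_give_identical_genetic_values(self, tiny_panel):
        arch = _one_factor_arch(np.array([1.0, 1.0]), [0.5, 0.5])
        G = simulate_genotypes(tiny_panel, 500, seed=0)
        phen = simulate_multitrait_phenotypes(G, arch, seed=0)
        gv = phen.genetic_values
        assert np.corrcoef(gv[:, 0], gv[:, 1])[0, 1] == pytest.approx(1.0)

    def test_zero_h2_trait_is_pure_environment(self, tiny_panel):
        arch = _one_factor_arch(np.array([0.7, 0.7]), [0.0, 0.5])
        G = simulate_genotypes(tiny_panel, 2000, seed=0)
        phen = simulate_multitrait_phenotypes(G, arch, seed=0)
        assert np.all(phen.genetic_values[:, 0] == 0)
        assert phen.realized_h2[0] == 0

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError, match="h2"):
            _one_factor_arch(np.array([0.7, 0.7]), [1.2, 0.5])

    def test_architecture_scale_constraint_enforced(self):
        with pytest.raises(ValueError, match="must equal 1"):
            TrueArchitecture(Lambda=np.array([[0.7], [0.7]]),
                             Psi=np.array([0.9, 0.9]), h2=np.array([0.5, 0.5]))

    def test_realized_h2_close_to_target(self, tiny_panel):
        arch = _one_factor_arch(np.array([0.7, 0.6]), [0.3, 0.6])
        G = simulate_genotypes(tiny_panel, 20000, seed=1)
        phen = simulate_multitrait_phenotypes(G, arch, seed=1)
        assert phen.realized_h2 == pytest.approx([0.3, 0.6], abs=0.02)

    def test_liability_threshold_prevalence(self, tiny_panel):
        arch = _one_factor_arch(np.array([0.7, 0.7]), [0.5, 0.5],
                                prevalence=np.array([0.1, np.nan]))
        G = simulate_genotypes(tiny_panel, 5000, seed=2)
        phen = simulate_multitrait_phenotypes(G, arch, seed=2)
        assert np.nanmean(phen.Ybin[:, 0]) == pytest.approx(0.1, abs=0.01)
        assert np.all(np.isnan(phen.Ybin[:, 1]))


class TestRunGwas:
    def test_null_phenotype_calibration(self, tiny_panel):
        rng = np.random.default_rng(0)
        G = simulate_genotypes(tiny_panel, 2000, seed=0)
        y = rng.standard_normal(2000)   # independent of genotype
        ss = run_gwas(G, y, tiny_panel)
        frac = (ss.table["P"] < 0.05).mean()
        # 50 SNPs, correlated in blocks: generous binomial band
        assert frac < 0.25

    def test_null_trait_mean_chisq(self):
        """Genome-scale null calibration: expected mean chi-square within
        [0.97, 1.03] at n = 20000, m = 2000.

        A single null scan's mean chi-square has sd ~ sqrt(2 l_bar / m)
        (LD correlates the per-SNP statistics), so the expectation is
        estimated over 20 independent null phenotypes on one genome.
        """
        panel = simulate_ld_panel(block_sizes=[25] * 80,
                                  rhos=[0.0, 0.3, 0.5, 0.7, 0.85] * 16,
                                  m=2000, seed=9)
        G = simulate_genotypes(panel, 20000, seed=9)
        rng = np.random.default_rng(9)
        means = []
        for _ in range(20):
            y = rng.standard_normal(20000)
            ss = run_gwas(G, y, panel)
            means.append(np.mean(ss.z ** 2))
        assert 0.97 <= np.mean(means) <= 1.03

    def test_single_causal_snp_dominates(self, tiny_panel):
        G = simulate_genotypes(tiny_panel, 5000, seed=1)
        y = 2.0 * G[:, 17].astype(float) + np.random.default_rng(1).standard_normal(5000)
        ss = run_gwas(G, y, tiny_panel)
        assert ss.table["P"].idxmin() == 17

    def test_beta_matches_closed_form_ols(self, tiny_panel):
        rng = np.random.default_rng(3)
        G = simulate_genotypes(tiny_panel, 300, seed=3)
        y = 0.4 * G[:, 0] + rng.standard_normal(300)
        ss = run_gwas(G, y, tiny_panel)
        x = G[:, 0].astype(float)
        b_expected = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        assert ss.table.loc[0, "BETA"] == pytest.approx(b_expected, rel=1e-10)
        # for standardized x and y the slope is the Pearson correlation
        xs = (x - x.mean()) / x.std()
        ys = (y - y.mean()) / y.std()
        r = np.corrcoef(x, y)[0, 1]
        assert np.sum(xs * ys) / np.sum(xs * xs) == pytest.approx(r, rel=1e-12)

    def test_monomorphic_snp_flagged(self, tiny_panel):
        G = simulate_genotypes(tiny_panel, 200, seed=4)
        G[:, 5] = 0
        y = np.random.default_rng(4).standard_normal(200)
        ss = run_gwas(G, y, tiny_panel)
        assert np.isnan(ss.table.loc[5, "BETA"])
        assert ss.meta["n_monomorphic"] == 1

    def test_minimum_sample_size(self, tiny_panel):
        G = simulate_genotypes(tiny_panel, 10, seed=0)
        with pytest.raises(ValueError, match=">= 30"):
            run_gwas(G, np.zeros(10), tiny_panel)


class TestGwasSuite:
    def test_duplicated_cohort_gives_identical_zscores(self, tiny_panel):
        arch = _one_factor_arch(np.array([0.7, 0.7]), [0.5, 0.5])
        specs = [CohortSpec(trait=0, n=500),
                 CohortSpec(trait=0, n=500, overlap={0: 1.0})]
        suite = make_gwas_suite(tiny_panel, arch, specs, seed=0)
        assert suite.sumstats[0].z == pytest.approx(suite.sumstats[1].z)
        assert suite.truth.overlap_n[0, 1] == 500

    def test_population_cap_enforced(self, tiny_panel):
        arch = _one_factor_arch(np.array([0.7, 0.7]), [0.5, 0.5])
        specs = [CohortSpec(trait=0, n=500), CohortSpec(trait=1, n=600)]
        with pytest.raises(ValueError, match="exceeds configured population"):
            make_gwas_suite(tiny_panel, arch, specs, seed=0, population_size=1000)

    def test_suite_determinism(self, tiny_panel):
        arch = _one_factor_arch(np.array([0.7, 0.7]), [0.5, 0.5])
        specs = [CohortSpec(trait=0, n=300), CohortSpec(trait=1, n=300)]
        a = make_gwas_suite(tiny_panel, arch, specs, seed=3)
        b = make_gwas_suite(tiny_panel, arch, specs, seed=3)
        for sa, sb in zip(a.sumstats, b.sumstats):
            assert sa.table.equals(sb.table)

    def test_case_control_cohort(self, tiny_panel):
        arch = _one_factor_arch(np.array([0.7, 0.7]), [0.5, 0.5],
                                prevalence=np.array([0.2, np.nan]))
        specs = [CohortSpec(trait=0, n=400, kind="case-control", case_fraction=0.5)]
        suite = make_gwas_suite(tiny_panel, arch, specs, seed=1)
        assert suite.sumstats[0].meta["binary"]
        assert len(suite.sumstats[0]) == tiny_panel.m

    def test_allele_flip_corruption_marks_rows(self, tiny_panel):
        arch = _one_factor_arch(np.array([0.7, 0.7]), [0.5, 0.5])
        specs = [CohortSpec(trait=0, n=300, flip_fraction=0.5)]
        suite = make_gwas_suite(tiny_panel, arch, specs, seed=2)
        t = suite.sumstats[0].table
        assert 0 < (t["A1"] == "G").sum() < tiny_panel.m

    def test_expected_cross_intercept_recorded(self, tiny_panel):
        arch = _one_factor_arch(np.array([0.7, 0.7]), [0.5, 0.5])
        specs = [CohortSpec(trait=0, n=400),
                 CohortSpec(trait=0, n=400, overlap={0: 0.5})]
        suite = make_gwas_suite(tiny_panel, arch, specs, seed=3)
        # same trait, shared individuals: r = 1, expected Ns/N = 0.5
        assert suite.truth.expected_cross_intercept[0, 1] == pytest.approx(0.5)


class TestTargetCohort:
    def test_population_target_has_covariates_and_counts(self, small_suite):
        G, pheno = simulate_target_cohort(small_suite.panel, small_suite.truth,
                                          300, seed=1)
        assert G.shape == (300, small_suite.panel.m)
        for col in ("trait0", "trait1", "sex", "age", "PC1", "PC10"):
            assert col in pheno.columns
        assert (pheno["trait0"] >= 0).all()   # symptom counts

    def test_ascertained_sample_is_all_cases(self):
        panel = simulate_ld_panel(block_sizes=[10] * 5, rhos=0.3, m=50, seed=5)
        Lam = np.array([[0.7], [0.7]])
        arch = TrueArchitecture(Lambda=Lam, Psi=1 - (Lam @ Lam.T).diagonal(),
                                h2=np.array([0.5, 0.5]),
                                prevalence=np.array([0.3, np.nan]))
        specs = [CohortSpec(trait=0, n=500, kind="case-control")]
        suite = make_gwas_suite(panel, arch, specs, seed=5)
        G, pheno = simulate_target_cohort(panel, suite.truth, 200, seed=5,
                                          ascertain_cases_for=0)
        assert len(pheno) == 200
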