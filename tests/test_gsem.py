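"""Genomic SEM layer: smoothing, EFA, CFA specification, DWLS fitting,
model comparison, SNP edges."""

import numpy as np
import pytest

from pgsem.gsem import (GenomicSEM, SEMModel, cfa_spec_from_efa,
                        compare_cfa_models, efa_extract, smooth_pd)
from pgsem.ldsc import CovStructure
from pgsem.sumstats import harmonize

from conftest import make_sumstats


def _cov(S, v_scale=1e-4, traits=None):
    k = S.shape[0]
    p = k * (k + 1) // 2
    return CovStructure(S=S, V=np.eye(p) * v_scale, I=np.eye(k), M=2000,
                        traits=traits or [f"t{i}" for i in range(k)])


def _one_factor_S(lam):
    lam = np.asarray(lam, float)
    return np.outer(lam, lam) + np.diag(1 - lam ** 2)


class TestSmoothPD:
    def test_pd_input_returned_exactly(self):
        S = _one_factor_S([0.8, 0.7, 0.6])
        S1, V1, change = smooth_pd(S, None)
        assert np.array_equal(S1, S)
        assert change == 0.0

    def test_clipping_engages_on_invalid_correlation(self):
        S = np.array([[1.0, 1.2], [1.2, 1.0]])
        S1, _, change = smooth_pd(S)
        assert abs(S1[0, 1]) < 1.0
        assert np.linalg.eigvalsh(S1).min() >= 0
        assert change > 0

    def test_matches_eigen_clip_oracle_on_indefinite_matrix(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((5, 5))
        S = (A + A.T) / 2
        np.fill_diagonal(S, np.abs(np.diag(S)) + 0.5)
        S1, _, _ = smooth_pd(S, eps=1e-6)
        # independent oracle: clip eigenvalues on the correlation scale,
        # renormalize the diagonal, rescale back
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        w, U = np.linalg.eigh(R)
        R1 = U @ np.diag(np.maximum(w, 1e-6)) @ U.T
        R1 = R1 / np.sqrt(np.outer(np.diag(R1), np.diag(R1)))
        expected = R1 * np.outer(d, d)
        assert S1 == pytest.approx(expected, abs=1e-10)
        assert np.diag(S1) == pytest.approx(np.diag(S))

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            smooth_pd(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestEFA:
    def test_identity_has_no_common_variance(self):
        S = np.eye(6)
        res = efa_extract(S, 2)
        assert np.abs(res.loadings).max() < 0.05
        assert res.eigenvalues == pytest.approx(np.ones(6))

    def test_clean_two_factor_recovery(self):
        L = np.zeros((8, 2))
        L[:4, 0] = [0.8, 0.75, 0.7, 0.65]
        L[4:, 1] = [0.8, 0.7, 0.75, 0.6]
        Phi = np.array([[1, 0.3], [0.3, 1.0]])
        S = L @ Phi @ L.T + np.diag(1 - np.diag(L @ Phi @ L.T))
        res = efa_extract(S, 2)
        # match up to column permutation and sign
        got = np.abs(res.loadings)
        cols = [np.argmax(got[0]), np.argmax(got[4])]
        aligned = got[:, cols]
        assert aligned == pytest.approx(np.abs(L), abs=0.02)
        assert abs(res.factor_corr[0, 1]) == pytest.approx(0.3, abs=0.02)

    def test_eigenvalue_rule_on_three_factor_structure(self):
        from pgsem.studies import three_factor_architecture
        arch = three_factor_architecture()
        res = efa_extract(arch.genetic_correlation(), 3)
        assert res.n_eigen_gt1 == 3

    @pytest.mark.parametrize("q", [0, 1, 6])
    def test_factor_range_enforced(self, q):
        with pytest.raises(ValueError):
            efa_extract(np.eye(6), q)


class TestCFASpec:
    def _efa_with_loadings(self, L):
        from pgsem.gsem import EFAResult
        L = np.asarray(L, float)
        k, q = L.shape
        return EFAResult(n_factors=q, loadings=np.asarray(L, float),
                         factor_corr=np.eye(q), eigenvalues=np.ones(k),
                         communalities=np.zeros(k),
                         traits=[f"t{i}" for i in range(k)])

    def test_cutoff_rule(self):
        efa = self._efa_with_loadings([[0.8, 0.05], [0.1, 0.9], [0.7, 0.1],
                                       [0.05, 0.75]])
        model = cfa_spec_from_efa(efa, cutoff=0.30)
        assert model.pattern[0].tolist() == [True, False]

    def test_orphan_assigned_to_highest_loading_factor(self):
        efa = self._efa_with_loadings([[0.8, 0.05], [0.1, 0.9], [0.25, 0.10],
                                       [0.05, 0.75]])
        model = cfa_spec_from_efa(efa, cutoff=0.30)
        assert model.pattern[2].tolist() == [True, False]

    def test_cross_loading_kept_when_both_exceed_cutoff(self):
        efa = self._efa_with_loadings([[0.5, 0.4], [0.8, 0.0], [0.0, 0.8],
                                       [0.6, 0.0]])
        model = cfa_spec_from_efa(efa, cutoff=0.30)
        assert model.pattern[0].tolist() == [True, True]

    def test_empty_factor_dropped(self):
        efa = self._efa_with_loadings([[0.8, 0.1], [0.7, 0.05], [0.75, 0.0],
                                       [0.6, 0.02]])
        model = cfa_spec_from_efa(efa, cutoff=0.30)
        assert model.q == 1

    def test_unidentified_model_rejected(self):
        with pytest.raises(ValueError, match="identified"):
            SEMModel(pattern=np.ones((3, 3), bool), traits=list("abc"),
                     factors=["F1", "F2", "F3"])

    def test_trait_without_factor_rejected(self):
        pattern = np.array([[True], [False]])
        with pytest.raises(ValueError, match="no factor"):
            SEMModel(pattern=pattern, traits=list("ab"), factors=["F1"])


class TestDWLSFit:
    def test_exact_fit_identity(self):
        lam = np.array([0.8, 0.7, 0.75, 0.65])
        cov = _cov(_one_factor_S(lam))
        fit = GenomicSEM(cov, SEMModel.unidimensional(cov.traits)).fit()
        assert fit.chi2 < 1e-8
        assert fit.cfi == 1.0
        assert fit.srmr < 1e-6
        assert np.abs(np.abs(fit.Lambda[:, 0]) - lam).max() < 1e-4
        assert fit.df == 2

    def test_gradient_norm_at_convergence(self):
        lam = np.array([0.8, 0.7, 0.75, 0.65])
        cov = _cov(_one_factor_S(lam))
        fit = GenomicSEM(cov, SEMModel.unidimensional(cov.traits)).fit()
        assert fit.grad_norm < 1e-6

    def test_restart_stability(self):
        """Five extra random restarts land on the same minimum."""
        rng = np.random.default_rng(1)
        lam = np.array([0.75, 0.7, 0.6, 0.65, 0.5])
        S = _one_factor_S(lam) + 0.01 * rng.standard_normal((5, 5))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        cov = _cov(S)
        model = SEMModel.unidimensional(cov.traits)
        f0 = GenomicSEM(cov, model).fit(n_restarts=0)
        f5 = GenomicSEM(cov, model).fit(n_restarts=5, seed=7)
        assert abs(f0.cost - f5.cost) < 1e-8

    def test_two_factor_structure_recovered(self):
        L = np.zeros((6, 2))
        L[:3, 0] = [0.8, 0.7, 0.6]
        L[3:, 1] = [0.75, 0.7, 0.65]
        Phi = np.array([[1, 0.4], [0.4, 1.0]])
        S = L @ Phi @ L.T + np.diag(1 - np.diag(L @ Phi @ L.T))
        cov = _cov(S)
        model = SEMModel(pattern=L != 0, traits=cov.traits, factors=["F1", "F2"])
        fit = GenomicSEM(cov, model).fit()
        assert np.abs(fit.Lambda[fit.Lambda != 0]) == pytest.approx(
            L[L != 0], abs=1e-4)
        assert abs(fit.Phi[0, 1]) == pytest.approx(0.4, abs=1e-4)

    def test_sandwich_se_reasonable(self):
        cov = _cov(_one_factor_S(np.array([0.8, 0.7, 0.75, 0.65])), v_scale=1e-4)
        fit = GenomicSEM(cov, SEMModel.unidimensional(cov.traits)).fit()
        assert np.all(fit.bse > 0)
        assert np.all(fit.bse < 0.1)

    def test_summary_renders(self):
        cov = _cov(_one_factor_S(np.array([0.8, 0.7, 0.6, 0.5])))
        fit = GenomicSEM(cov, SEMModel.unidimensional(cov.traits)).fit()
        text = fit.summary()
        assert "CFI" in text and "SRMR" in text and "loading" in text


class TestModelComparison:
    def test_single_model_table(self):
        cov = _cov(_one_factor_S(np.array([0.8, 0.7, 0.6, 0.5])))
        fit = GenomicSEM(cov, SEMModel.unidimensional(cov.traits)).fit()
        table = compare_cfa_models([fit])
        assert len(table) == 1

    def test_parsimony_breaks_equal_fit(self):
        """Data generated by one factor: both the 1- and 2-factor models fit
        exactly, so AIC must rank the smaller model first."""
        S = _one_factor_S(np.array([0.8, 0.75, 0.7, 0.65, 0.6]))
        cov = _cov(S)
        m1 = SEMModel.unidimensional(cov.traits)
        pattern2 = np.zeros((5, 2), bool)
        pattern2[:3, 0] = True
        pattern2[2:, 1] = True
        m2 = SEMModel(pattern=pattern2, traits=cov.traits, factors=["F1", "F2"])
        f1 = GenomicSEM(cov, m1).fit()
        f2 = GenomicSEM(cov, m2).fit(n_restarts=6)
        table = compare_cfa_models([f2, f1])
        assert table.iloc[0]["n_free"] == f1.n_free

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compare_cfa_models([])


@pytest.fixture(scope="module")
def fitted():
    lam = np.array([0.75, 0.75, 0.8, 0.7])
    cov = _cov(_one_factor_S(lam) * 0.4, v_scale=1e-5)
    return GenomicSEM(cov, SEMModel.unidimensional(cov.traits)).fit()


class TestSNPEdges:

    def test_null_snp_gives_zero_paths(self, fitted):
        members = [make_sumstats(10, seed=t, BETA=np.zeros(10),
                                 SE=np.full(10, 0.01)) for t in range(4)]
        for t, m in enumerate(members):
            m.trait = f"t{t}"
        hset = harmonize(members)
        edges = fitted.snp_edges(hset, factor=0, residual_traits=[0, 1])
        assert np.all(edges.est == 0)

    def test_missing_snp_skipped_and_counted(self, fitted):
        members = [make_sumstats(10, seed=t, SE=np.full(10, 0.01))
                   for t in range(4)]
        members[2].table.loc[3, "BETA"] = np.nan
        hset = harmonize(members)
        edges = fitted.snp_edges(hset, factor=0, residual_traits=[0, 1])
        assert edges.n_skipped == 1
        assert np.isnan(edges.est[3]).all()

    def test_output_sumstats_dialect(self, fitted):
        members = [make_sumstats(40, seed=t, SE=np.full(40, 0.01))
                   for t in range(4)]
        hset = harmonize(members)
        edges = fitted.snp_edges(hset, factor=0, residual_traits=[0, 1])
        out = edges.to_sumstats("residual:t0")
        out.validate()
        assert len(out) == 40
        assert (out.table["N"] > 0).all()

    def test_dimension_mismatch_rejected(self, fitted):
        members = [make_sumstats(10, seed=t) for t in range(3)]
        hset = harmonize(members)
        with pytest.raises(ValueError, match="mismatch"):
            fitted.snp_edges(hset, factor=0, residual_traits=[0])
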