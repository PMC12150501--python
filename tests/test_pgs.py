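"""Clumping, summary-statistic subsampling, threshold tuning, scoring."""

import numpy as np
import pandas as pd
import pytest

from pgsem.pgs import (PGSWeights, clump, compute_pgs, cv_select_threshold,
                       subsample_sumstats)
from pgsem.simulate import simulate_ld_panel
from pgsem.sumstats import SumStats

from conftest import make_sumstats


def greedy_clump_oracle(pvals, positions, chroms, R, window_bp, r2_max):
    """Deliberately naive re-implementation of the greedy clumping rule."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: (pvals[i], chroms[i], positions[i]))
    claimed = [False] * m
    picked = []
    for i in order:
        if claimed[i]:
            continue
        picked.append(i)
        claimed[i] = True
        for j in range(m):
            if claimed[j] or chroms[j] != chroms[i]:
                continue
            if abs(positions[j] - positions[i]) <= window_bp and R[i, j] ** 2 > r2_max:
                claimed[j] = True
    return picked


def _sumstats_on_panel(panel, pvals, seed=0):
    ss = make_sumstats(panel.m, seed=seed)
    t = ss.table
    t["BP"] = panel.positions
    t["P"] = pvals
    z = np.abs(np.asarray(t["BETA"] / t["SE"]))
    # keep P free-form for clumping tests (no z consistency needed there)
    return SumStats(t, trait="clumptest")


class TestClump:
    def test_single_snp_retained(self):
        panel = simulate_ld_panel(block_sizes=[1], rhos=[0.0], seed=0)
        ss = _sumstats_on_panel(panel, [0.5])
        out = clump(ss, panel)
        assert len(out) == 1

    def test_correlated_pair_keeps_smaller_p(self):
        panel = simulate_ld_panel(block_sizes=[2], rhos=[0.8], seed=0)  # r2 0.64
        ss = _sumstats_on_panel(panel, [0.3, 0.01])
        out = clump(ss, panel, r2_max=0.1)
        assert list(out.table["SNP"]) == ["rs2"]

    def test_uncorrelated_pair_both_kept(self):
        panel = simulate_ld_panel(block_sizes=[1, 1], rhos=[0.0, 0.0], seed=0)
        ss = _sumstats_on_panel(panel, [0.3, 0.01])
        out = clump(ss, panel, r2_max=0.1)
        assert len(out) == 2

    def test_matches_greedy_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for rep in range(50):
            panel = simulate_ld_panel(block_sizes=[5, 5, 5, 5],
                                      rhos=list(rng.uniform(0, 0.95, 4)),
                                      seed=rep)
            pvals = rng.uniform(size=20)
            ss = _sumstats_on_panel(panel, pvals, seed=rep)
            out = clump(ss, panel, window_kb=rng.choice([10, 50, 1000]),
                        r2_max=rng.choice([0.1, 0.3, 0.5]))
            # reconstruct the call's parameters for the oracle
            wkb = out.meta["clump_window_kb"] * 1000
            r2m = out.meta["clump_r2"]
            expected = greedy_clump_oracle(pvals, panel.positions,
                                           [1] * 20, panel.R, wkb, r2m)
            assert list(out.table.index) == list(range(len(expected)))
            assert list(out.table["SNP"]) == [f"rs{i + 1}" for i in expected]

    def test_row_order_invariance(self):
        panel = simulate_ld_panel(block_sizes=[10, 10], rhos=[0.7, 0.4], seed=1)
        pvals = np.random.default_rng(1).uniform(size=20)
        ss = _sumstats_on_panel(panel, pvals, seed=1)
        shuffled = SumStats(ss.table.sample(frac=1, random_state=3)
                            .reset_index(drop=True), trait="x")
        a = clump(ss, panel)
        b = clump(shuffled, panel)
        assert list(a.table["SNP"]) == list(b.table["SNP"])

    def test_threshold_nesting(self):
        """SNP set at p <= t1 is a subset of the set at t2 >= t1 on the same
        clumped universe."""
        panel = simulate_ld_panel(block_sizes=[10] * 4, rhos=[0.5] * 4, seed=2)
        pvals = np.random.default_rng(2).uniform(size=40)
        ss = _sumstats_on_panel(panel, pvals, seed=2)
        clumped = clump(ss, panel)
        w1 = PGSWeights.from_sumstats(clumped, threshold=0.2)
        w2 = PGSWeights.from_sumstats(clumped, threshold=0.6)
        assert set(w1.table["SNP"]) <= set(w2.table["SNP"])


class TestSubsample:
    def test_conservation_identity_exact(self):
        ss = make_sumstats(50, seed=3)
        tr, te = subsample_sumstats(ss, 0.75, seed=0)
        N = ss.table["N"].to_numpy(float)
        r_hat = ss.z / np.sqrt(N)
        lhs = (tr.table["N"] * tr.table["BETA"] + te.table["N"] * te.table["BETA"])
        assert lhs.to_numpy() == pytest.approx(N * r_hat, rel=1e-12)

    def test_degenerate_split_reproduces_input(self):
        ss = make_sumstats(50, seed=4)
        tr, _ = subsample_sumstats(ss, 0.999999, seed=0)
        r_hat = ss.z / np.sqrt(ss.table["N"].to_numpy(float))
        assert tr.table["BETA"].to_numpy() == pytest.approx(r_hat, abs=1e-4)

    def test_test_effect_unbiased(self):
        ss = make_sumstats(20, seed=5)
        N = ss.table["N"].to_numpy(float)
        r_hat = ss.z / np.sqrt(N)
        draws = np.stack([subsample_sumstats(ss, 0.75, seed=s)[1]
                          .table["BETA"].to_numpy() for s in range(1000)])
        mc_mean = draws.mean(axis=0)
        mc_se = draws.std(axis=0) / np.sqrt(1000)
        assert np.all(np.abs(mc_mean - r_hat) < 4 * mc_se + 1e-12)

    def test_missing_n_errors_with_snp_names(self):
        ss = make_sumstats(5, seed=6)
        ss.table.loc[2, "N"] = np.nan
        with pytest.raises(ValueError, match="rs3"):
            subsample_sumstats(ss, 0.75, seed=0)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_invalid_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            subsample_sumstats(make_sumstats(5), frac, seed=0)


class TestThresholdCV:
    def test_null_sumstats_r2_near_zero(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal(500)
        ss = make_sumstats(500, seed=7, BETA=z * 0.01, SE=np.full(500, 0.01),
                           N=10000.0)
        cv = cv_select_threshold(ss, folds=4, seed=0)
        assert np.all(cv.mean_r2 < 0.01)

    def test_zero_snp_threshold_scores_zero(self):
        z = np.full(20, 0.5)
        ss = make_sumstats(20, seed=8, BETA=z * 0.01, SE=np.full(20, 0.01),
                           N=10000.0)
        cv = cv_select_threshold(ss, thresholds=[1.0, 1e-30], folds=2, seed=0)
        assert cv.mean_r2[1] == 0.0

    def test_selected_is_argmax_and_frame_renders(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal(300) + 2.0
        ss = make_sumstats(300, seed=9, BETA=z * 0.01, SE=np.full(300, 0.01),
                           N=10000.0)
        cv = cv_select_threshold(ss, folds=4, seed=1)
        assert cv.selected == cv.thresholds[int(np.argmax(cv.mean_r2))]
        assert cv.as_frame().shape == (5, len(cv.thresholds))


class TestComputePGS:
    def _weights(self, snps, a1, w, p=None):
        table = pd.DataFrame({"SNP": snps, "A1": a1, "weight": w,
                              "p_source": p or [0.01] * len(snps),
                              "CHR": 1, "BP": range(len(snps))})
        return PGSWeights(table=table, threshold=1.0)

    def test_hand_worked_scores_with_allele_flip(self):
        # 3 SNPs x 4 individuals; weight for rs2 keyed to the other allele
        G = np.array([[0, 1, 2], [1, 0, 0], [2, 2, 1], [0, 1, 1]], dtype=np.int8)
        w = self._weights(["rs1", "rs2", "rs3"], ["A", "G", "A"], [0.5, 1.0, -0.2])
        out = compute_pgs(w, G, ["rs1", "rs2", "rs3"], ["A", "A", "A"],
                          ["G", "G", "G"], standardize=False)
        # rs2 flipped: dosage 2 - d
        expected = (0.5 * G[:, 0] + 1.0 * (2 - G[:, 1]) - 0.2 * G[:, 2])
        assert out["score"].to_numpy() == pytest.approx(expected)

    def test_single_snp_identity(self):
        G = np.array([[0], [1], [2], [1]], dtype=np.int8)
        w = self._weights(["rs1"], ["A"], [1.0])
        out = compute_pgs(w, G, ["rs1"], ["A"], ["G"])
        d = G[:, 0].astype(float)
        assert out["score"].to_numpy() == pytest.approx((d - d.mean()) / d.std())

    def test_zero_weights_warns_and_returns_unstandardized(self, caplog):
        G = np.array([[0, 1], [1, 2]], dtype=np.int8)
        w = self._weights(["rs1", "rs2"], ["A", "A"], [0.0, 0.0])
        with caplog.at_level("WARNING"):
            out = compute_pgs(w, G, ["rs1", "rs2"], ["A", "A"], ["G", "G"])
        assert np.all(out["score"] == 0)
        assert "zero score variance" in caplog.text

    def test_missing_snps_dropped(self):
        G = np.array([[0], [2]], dtype=np.int8)
        w = self._weights(["rs1", "rsX"], ["A", "A"], [1.0, 5.0])
        out = compute_pgs(w, G, ["rs1"], ["A"], ["G"], standardize=False)
        assert out["score"].to_numpy() == pytest.approx([0.0, 2.0])

    def test_unalignable_alleles_dropped(self):
        G = np.array([[1, 1], [2, 0]], dtype=np.int8)
        w = self._weights(["rs1", "rs2"], ["A", "C"], [1.0, 9.0])
        out = compute_pgs(w, G, ["rs1", "rs2"], ["A", "A"], ["G", "G"],
                          standardize=False)
        assert out["score"].to_numpy() == pytest.approx([1.0, 2.0])

    def test_nan_dosages_mean_imputed(self):
        G = np.array([[0.0, 1], [np.nan, 2], [2.0, 0]])
        w = self._weights(["rs1"], ["A"], [1.0])
        out = compute_pgs(w, G, ["rs1", "rs2"], ["A", "A"], ["G", "G"],
                          standardize=False)
        assert out["score"].to_numpy() == pytest.approx([0.0, 1.0, 2.0])
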