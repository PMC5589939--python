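import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from brainmux.stats import (
    fdr_adjust,
    hierarchical_test,
    kruskal_wallis,
    nodewise_group_test,
    permutation_ttest,
    spearman_correlation,
)
from oracles import fdr_stepup_oracle, spearman_oracle


class TestPermutationTTest:
    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = permutation_ttest(x, x.copy(), B=500, seed=0)
        assert res.p == 1.0

    def test_swapping_groups_negates_statistic(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(1, 1, 20)
        r1 = permutation_ttest(x, y, B=2000, seed=0)
        r2 = permutation_ttest(y, x, B=2000, seed=0)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.z == pytest.approx(-r2.z, abs=0.25)
        assert r1.p == pytest.approx(r2.p, abs=0.02)

    def test_strong_effect_small_p(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 25)
        y = rng.normal(3, 1, 25)
        res = permutation_ttest(x, y, B=10000, seed=0)
        assert res.p <= 0.001

    def test_p_bounded_below(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(10, 1, 10)
        res = permutation_ttest(x, y, B=100, seed=0)
        assert res.p >= 1.0 / 101.0
        assert res.p > 0.0

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = permutation_ttest(np.ones(5), np.ones(5), B=100)
        assert res.p == 1.0 and res.z == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            permutation_ttest(np.array([1.0]), np.ones(5))

    def test_deterministic_under_seed(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        r1 = permutation_ttest(x, y, B=500, seed=9)
        r2 = permutation_ttest(x, y, B=500, seed=9)
        assert (r1.p, r1.z) == (r2.p, r2.z)


class TestNodewise:
    def test_null_calibration(self):
        # all-null nodes: ~5% of p-values below 0.05
        rng = np.random.default_rng(7)
        feats = rng.normal(size=(40, 200))
        labels = np.array(["AD"] * 20 + ["HC"] * 20)
        res = nodewise_group_test(feats, labels, B=400, seed=1)
        frac = np.mean([r.p < 0.05 for r in res])
        assert 0.02 <= frac <= 0.09

    def test_planted_node_has_smallest_p(self):
        rng = np.random.default_rng(3)
        feats = rng.normal(size=(30, 20))
        labels = np.array(["AD"] * 15 + ["HC"] * 15)
        feats[:15, 7] += 2.5
        res = nodewise_group_test(feats, labels, B=2000, seed=2)
        ps = np.array([r.p for r in res])
        assert np.argmin(ps) == 7

    def test_constant_node_warns_nonsignificant(self, rng):
        feats = rng.normal(size=(20, 3))
        feats[:, 1] = 5.0
        labels = np.array(["AD"] * 10 + ["HC"] * 10)
        with pytest.warns(UserWarning, match="constant"):
            res = nodewise_group_test(feats, labels, B=200, seed=0)
        assert res[1].p == 1.0

    def test_missing_values_rejected(self, rng):
        feats = rng.normal(size=(10, 2))
        feats[0, 0] = np.nan
        labels = np.array(["AD"] * 5 + ["HC"] * 5)
        with pytest.raises(ValueError, match="missing"):
            nodewise_group_test(feats, labels)

    def test_matches_scalar_test(self, rng):
        # the vectorized node-wise path must agree with the single-feature API
        feats = rng.normal(size=(24, 4))
        labels = np.array(["AD"] * 12 + ["HC"] * 12)
        multi = nodewise_group_test(feats, labels, B=500, seed=5)
        solo = permutation_ttest(feats[:12, 2], feats[12:, 2], B=500, seed=5)
        assert multi[2].statistic == pytest.approx(solo.statistic)
        assert multi[2].p == pytest.approx(solo.p)


class TestFDR:
    def test_single_pvalue(self):
        reject, adj = fdr_adjust(np.array([0.04]), q=0.05)
        assert reject[0]
        reject, _ = fdr_adjust(np.array([0.06]), q=0.05)
        assert not reject[0]

    def test_all_small_all_rejected(self):
        p = np.full(148, 0.001)
        reject, _ = fdr_adjust(p, q=0.05)
        assert reject.all()

    def test_matches_stepup_oracle(self, rng):
        for _ in range(30):
            m = int(rng.integers(1, 60))
            p = rng.random(m).clip(1e-9, 1.0)
            reject, _ = fdr_adjust(p, q=0.05)
            assert np.array_equal(reject, fdr_stepup_oracle(p, 0.05))

    def test_matches_statsmodels(self, rng):
        for method, sm_name in (("bh", "fdr_bh"), ("by", "fdr_by")):
            p = rng.random(50).clip(1e-9, 1.0)
            reject, adj = fdr_adjust(p, q=0.05, method=method)
            sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.05, method=sm_name)
            assert np.array_equal(reject, sm_rej)
            assert np.allclose(adj, sm_adj)

    def test_adjusted_monotone_in_raw(self, rng):
        p = rng.random(40).clip(1e-9, 1.0)
        _, adj = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.random(30).clip(1e-9, 1.0)
        reject, adj = fdr_adjust(p)
        perm = rng.permutation(30)
        reject_p, adj_p = fdr_adjust(p[perm])
        assert np.array_equal(reject_p, reject[perm])
        assert np.allclose(adj_p, adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            fdr_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ValueError, match="p-values"):
            fdr_adjust(np.array([1.1]))


class TestSpearman:
    def test_monotone_increasing_r_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        y = x**3
        r, _ = spearman_correlation(x, y, B=100, seed=0)
        assert r == pytest.approx(1.0)

    def test_monotone_decreasing_r_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r, _ = spearman_correlation(x, -x, B=100, seed=0)
        assert r == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self, rng):
        x = rng.integers(0, 5, 30).astype(float)  # heavy ties
        y = rng.integers(0, 5, 30).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            pytest.skip("degenerate draw")
        r, _ = spearman_correlation(x, y, B=100, seed=0)
        assert r == pytest.approx(spearman_oracle(x, y), abs=1e-12)
        assert r == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_permutation_p_consistent_with_effect(self, rng):
        x = np.linspace(0, 1, 30)
        y = x + rng.normal(0, 0.1, 30)
        _, p = spearman_correlation(x, y, B=2000, seed=1)
        assert p < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation(np.ones(5), np.arange(5.0))


class TestKruskalWallis:
    def test_h_nonnegative(self, rng):
        groups = [rng.normal(size=8) for _ in range(4)]
        h, _ = kruskal_wallis(groups)
        assert h >= 0

    def test_matches_scipy(self, rng):
        for _ in range(10):
            groups = [rng.normal(size=int(rng.integers(5, 12))) for _ in range(3)]
            h, p = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert h == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_with_ties_matches_scipy(self, rng):
        groups = [rng.integers(0, 4, 10).astype(float) for _ in range(3)]
        h, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)

    def test_two_groups_equals_squared_ranksum(self, rng):
        # H (no ties) equals the squared standardized Wilcoxon rank-sum stat
        x = rng.normal(size=10)
        y = rng.normal(size=12)
        h, _ = kruskal_wallis([x, y])
        n, m = len(x), len(y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        w = ranks[:n].sum()
        mu = n * (n + m + 1) / 2.0
        sd = np.sqrt(n * m * (n + m + 1) / 12.0)
        assert h == pytest.approx(((w - mu) / sd) ** 2)

    def test_identical_values_h_zero(self):
        h, p = kruskal_wallis([np.ones(5), np.ones(6)])
        assert h == 0.0

    def test_null_p_roughly_uniform(self):
        ps = []
        for rep in range(60):
            r = np.random.default_rng(rep)
            ps.append(kruskal_wallis([r.normal(size=10) for _ in range(3)])[1])
        # mean of uniform ~0.5; crude calibration check
        assert 0.35 < np.mean(ps) < 0.65


class TestHierarchical:
    def _cohort(self, effect):
        rng = np.random.default_rng(11)
        n = 20
        local = rng.normal(size=(2 * n, 10))
        local[:n, 3] += effect
        global_x = local[:n].mean(axis=1)
        global_y = local[n:].mean(axis=1)
        labels = np.array(["AD"] * n + ["HC"] * n)
        return global_x, global_y, local, labels

    def test_nonsignificant_global_not_pursued(self):
        gx, gy, local, labels = self._cohort(effect=0.0)
        out = hierarchical_test(
            {"f": (gx, gy)}, {"f": (local, labels)}, B=400, seed=3
        )
        if out["f"]["global"].p >= 0.05:
            assert out["f"]["status"] == "not pursued"
            assert "local" not in out["f"]

    def test_significant_global_pursued_with_fdr(self):
        gx, gy, local, labels = self._cohort(effect=3.0)
        out = hierarchical_test(
            {"f": (gx, gy)}, {"f": (local, labels)}, B=400, seed=3
        )
        assert out["f"]["global"].p < 0.05
        assert out["f"]["status"] == "pursued"
        locs = out["f"]["local"]
        assert len(locs) == 10
        assert any(r.significant for r in locs)
        assert all(r.p_adjusted is not None for r in locs)

    def test_end_to_end_planted_effect_both_levels(self):
        gx, gy, local, labels = self._cohort(effect=4.0)
        out = hierarchical_test(
            {"f": (gx, gy)}, {"f": (local, labels)}, B=600, seed=5
        )
        assert out["f"]["global"].p < 0.05
        sig_nodes = [i for i, r in enumerate(out["f"]["local"]) if r.significant]
        assert 3 in sig_nodes
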