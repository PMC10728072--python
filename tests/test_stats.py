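"""Cluster permutation test, FDR, robust regression, coupling-score link."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats

from resposc.stats import cluster_test, coupling_reactivation, fdr_bh, robust_regress


class TestClusterTest:
    def test_identical_conditions_no_clusters(self, rng):
        a = rng.standard_normal((10, 30))
        res = cluster_test(a, a.copy(), n_permutations=200, seed=0)
        assert len(res.cluster_stats) == 0
        assert not res.significant_mask.any()

    def test_planted_block_recovered(self, rng):
        a = rng.standard_normal((20, 40))
        b = rng.standard_normal((20, 40))
        a[:, 10:20] += 2.0
        res = cluster_test(a, b, n_permutations=1000, seed=1)
        assert res.cluster_p.min() <= 0.002
        assert res.significant_mask[10:20].mean() >= 0.9

    def test_type_one_error_quick(self, rng):
        false_positives = 0
        n_sims = 60
        for _ in range(n_sims):
            a = rng.standard_normal((15, 30))
            b = rng.standard_normal((15, 30))
            res = cluster_test(a, b, n_permutations=300, seed=rng)
            false_positives += bool((res.cluster_p <= 0.05).any())
        assert false_positives / n_sims <= 0.15

    def test_participant_order_exchangeability(self, rng):
        a = rng.standard_normal((12, 25))
        b = rng.standard_normal((12, 25))
        a[:, 5:12] += 1.0
        res1 = cluster_test(a, b, n_permutations=300, seed=3)
        perm = rng.permutation(12)
        res2 = cluster_test(a[perm], b[perm], n_permutations=300, seed=3)
        np.testing.assert_allclose(res1.t_map, res2.t_map)
        np.testing.assert_array_equal(res1.cluster_labels, res2.cluster_labels)

    def test_seeded_reproducibility(self, rng):
        a = rng.standard_normal((10, 20))
        b = rng.standard_normal((10, 20))
        r1 = cluster_test(a, b, n_permutations=200, seed=7)
        r2 = cluster_test(a, b, n_permutations=200, seed=7)
        np.testing.assert_array_equal(r1.cluster_p, r2.cluster_p)

    def test_agrees_with_mne_reference(self, rng):
        from mne.stats import permutation_cluster_1samp_test

        d = rng.standard_normal((15, 30))
        d[:, 5:12] += 1.0
        threshold = sp_stats.t.ppf(1 - 0.025, 14)
        _, clusters, p_mne, _ = permutation_cluster_1samp_test(
            d, threshold=threshold, n_permutations=1000, tail=0, seed=0,
            out_type="mask", verbose="error")
        res = cluster_test(d, np.zeros_like(d), n_permutations=1000, seed=0)

        def to_mask(c):
            m = np.zeros(d.shape[1], bool)
            m[c[0] if isinstance(c, tuple) else np.asarray(c, bool)] = True
            return m

        mne_masks = [to_mask(c) for c in clusters]
        assert len(mne_masks) == len(res.cluster_stats)
        # same cluster extents and compatible Monte-Carlo p-values
        ours = [res.cluster_labels == k + 1 for k in range(len(res.cluster_stats))]
        for mask in mne_masks:
            assert any(np.array_equal(mask, m) for m in ours)
        assert abs(min(p_mne) - res.cluster_p.min()) < 0.01

    def test_channel_adjacency_merges_neighbouring_channels(self, rng):
        # effect on two adjacent channels (ring of 4) forms one cluster
        a = rng.standard_normal((15, 20, 4)) * 0.3
        b = rng.standard_normal((15, 20, 4)) * 0.3
        a[:, 8:14, 0] += 2.0
        a[:, 8:14, 1] += 2.0
        ring = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], bool)
        res = cluster_test(a, b, n_permutations=300, seed=0,
                           channel_adjacency=ring, channel_axis=1)
        labels_ch0 = set(res.cluster_labels[8:14, 0]) - {0}
        labels_ch1 = set(res.cluster_labels[8:14, 1]) - {0}
        assert labels_ch0 and labels_ch0 == labels_ch1

    def test_few_permutations_warns(self, rng):
        a = rng.standard_normal((6, 10))
        with pytest.warns(UserWarning, match="permutations"):
            cluster_test(a, a + 0.1, n_permutations=50, seed=0)


class TestFDR:
    def test_all_small_all_significant(self):
        assert fdr_bh(np.full(10, 0.001)).all()

    def test_step_up_rule_by_hand(self):
        mask = fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        np.testing.assert_array_equal(mask, [True, True, True, False])

    def test_all_one_none_significant(self):
        assert not fdr_bh(np.ones(8)).any()

    def test_no_rejection_when_min_p_above_q(self, rng):
        p = rng.uniform(0.06, 1.0, 12)
        assert not fdr_bh(p, q=0.05).any()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_monotone_in_q(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 15)
        lo = fdr_bh(p, q=0.01)
        hi = fdr_bh(p, q=0.10)
        assert np.all(hi[lo])  # everything rejected at q=0.01 stays rejected


def brute_force_irls(x, y, c=4.685, iters=100, tol=1e-10):
    """Independent IRLS with bisquare weights and MAD-about-zero scale."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    for _ in range(iters):
        r = y - X @ beta
        s = np.median(np.abs(r)) / 0.6744897501960817
        if s <= 0:
            break
        u = r / (c * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta  # (intercept, slope)


class TestRobustRegression:
    def test_perfect_line(self):
        x = np.linspace(0, 1, 12)
        res = robust_regress(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0, abs=1e-9)
        assert res.intercept == pytest.approx(1.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.weights, 1.0, atol=1e-6)

    def test_outlier_downweighted(self, rng):
        x = np.linspace(0, 1, 20)
        y_clean = 2 * x + 1 + rng.normal(0, 0.05, 20)
        clean_slope = np.polyfit(x, y_clean, 1)[0]
        y = y_clean.copy()
        y[-1] += 10.0
        naive_slope = np.polyfit(x, y, 1)[0]
        robust_slope = robust_regress(x, y).slope
        assert abs(robust_slope - clean_slope) < abs(naive_slope - clean_slope)

    def test_matches_brute_force_irls(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            x = rng.normal(size=n)
            y = 1 + 2 * x + rng.standard_t(3, size=n)
            res = robust_regress(x, y, max_iter=100, tol=1e-10)
            intercept, slope = brute_force_irls(x, y)
            assert abs(res.slope - slope) < 1e-6
            assert abs(res.intercept - intercept) < 1e-6

    def test_zero_variance_x_error(self):
        with pytest.raises(ValueError):
            robust_regress(np.ones(10), np.arange(10.0))

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            robust_regress(np.arange(3.0), np.arange(3.0))


class TestCouplingReactivation:
    @staticmethod
    def _tables(rng, n=20, channels=("F2", "C3", "P1", "O2"), effect_channel="F2",
                slope=0.2, noise=0.04):
        r_true = np.linspace(0.4, 0.95, n)
        rows = []
        for ch in channels:
            x = r_true if ch == effect_channel else rng.uniform(0.05, 0.3, n)
            rows.extend(dict(participant=f"p{i:02d}", channel=ch, vector_length=x[i])
                        for i in range(n))
        scores = pd.DataFrame({
            "participant": [f"p{i:02d}" for i in range(n)],
            "score": 0.55 + slope * r_true + rng.normal(0, noise, n),
        })
        return pd.DataFrame(rows), scores

    def test_planted_channel_found(self, rng):
        vl, scores = self._tables(rng, noise=0.01)
        table = coupling_reactivation(vl, scores)
        f2 = table[table["channel"] == "F2"].iloc[0]
        assert f2["significant"] and f2["slope"] > 0

    def test_shuffled_scores_rarely_significant(self):
        rng = np.random.default_rng(2)
        vl, scores = self._tables(rng, noise=0.01)
        n_sig = 0
        n_shuffles = 50
        for _ in range(n_shuffles):
            shuffled = scores.copy()
            shuffled["score"] = rng.permutation(shuffled["score"].to_numpy())
            n_sig += int(coupling_reactivation(vl, shuffled)["significant"].sum())
        assert n_sig / n_shuffles <= 0.05 * 4 + 0.15

    def test_single_channel_mask_equals_raw_decision(self, rng):
        vl, scores = self._tables(rng, channels=("F2",), noise=0.02)
        table = coupling_reactivation(vl, scores)
        assert bool(table["significant"].iloc[0]) == (table["p_value"].iloc[0] <= 0.05)

    def test_missing_score_dropped_with_warning(self, rng):
        vl, scores = self._tables(rng)
        with pytest.warns(UserWarning, match="without scores"):
            table = coupling_reactivation(vl, scores.iloc[:-1])
        assert (table["n"] == 19).all()
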