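"""Cluster-permutation engine tests: stats, clustering, null, p-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from conftest import make_pgi_binned, oracle_clusters
from patternglare.layouts import Layout, subset_layout, DEFAULT_4, DEFAULT_16
from patternglare.mua import (T_CAP, build_adjacency, cluster_pvalues,
                              effect_sizes, form_clusters, forming_threshold,
                              permutation_null, run_mua, samplewise_stat,
                              select_peak_electrode)
from patternglare.regressors import factor_regressor, intercept_regressor


class TestBuildAdjacency:
    def test_two_channels_one_edge_when_within_threshold(self):
        lay = Layout(("a", "b"), np.array([[0.0, 0.0], [0.3, 0.4]]))
        adj = build_adjacency(lay, 0.5)     # distance exactly 0.5
        assert len(adj.pairs) == 1

    def test_zero_threshold_edgeless_warns(self):
        lay = Layout(("a", "b"), np.array([[0.0, 0.0], [1.0, 0.0]]))
        with pytest.warns(UserWarning, match="edgeless"):
            adj = build_adjacency(lay, 0.0)
        assert len(adj.pairs) == 0

    def test_regular_grid_interior_degree_four(self):
        h = 0.2
        names, pos = [], []
        for i in range(5):
            for j in range(5):
                names.append(f"g{i}{j}")
                pos.append((i * h, j * h))
        for thr, degree in ((1.2 * h, 4), (1.5 * h, 8)):
            # 1.2h keeps rook moves only; 1.5h adds the sqrt(2)h diagonals
            adj = build_adjacency(Layout(tuple(names), np.array(pos)), thr)
            nb = adj.neighbor_matrix()
            # brute-force oracle over pairwise distances
            d = np.sqrt(((np.array(pos)[:, None]
                          - np.array(pos)[None]) ** 2).sum(-1))
            expected = (d <= thr) & ~np.eye(25, dtype=bool)
            assert np.array_equal(nb, expected)
            assert nb[names.index("g22")].sum() == degree


class TestSamplewiseStat:
    def test_one_sample_closed_form(self, tiny_layout):
        vals = np.zeros((3, 1, 1, 4, 2))
        vals[:, 0, 0, :, :] = np.array([1.0, 2.0, 3.0])[:, None, None]
        b = make_pgi_binned(vals, tiny_layout)
        sm = samplewise_stat(b, intercept_regressor(b.participants))
        assert np.allclose(sm.t, 2.0 / (1.0 / np.sqrt(3)))
        assert sm.df == 2

    def test_perfect_fit_capped_and_flagged(self, tiny_layout):
        x = np.array([0.1, 0.5, -0.3, 0.8, -0.6])
        vals = np.broadcast_to(x[:, None, None, None, None],
                               (5, 1, 1, 4, 3)).copy()
        b = make_pgi_binned(vals, tiny_layout)
        scores = pd.Series(x, index=b.participants)
        sm = samplewise_stat(b, factor_regressor(scores, "f"))
        assert np.all(np.abs(sm.t) == T_CAP)
        assert sm.capped == 12

    def test_null_t_values_follow_student_t(self, tiny_layout, rng):
        """Independent data: sample-wise t matches its nominal distribution."""
        n = 12
        vals = rng.standard_normal((n, 1, 1, 4, 2500))
        b = make_pgi_binned(vals, tiny_layout, sfreq=2500.0)
        scores = pd.Series(rng.standard_normal(n), index=b.participants)
        sm = samplewise_stat(b, factor_regressor(scores, "f"))
        stat, p = stats.kstest(sm.t.ravel(), "t", args=(n - 2,))
        assert p > 0.01

    def test_alignment_checked(self, tiny_layout, rng):
        vals = rng.standard_normal((4, 1, 1, 4, 5))
        b = make_pgi_binned(vals, tiny_layout)
        other = pd.Series(np.arange(4.0), index=list("wxyz"))
        with pytest.raises(ValueError, match="mismatch"):
            samplewise_stat(b, factor_regressor(other, "f"))


class TestFormClusters:
    def test_all_zero_map_no_clusters(self, tiny_layout, tiny_adjacency):
        b = make_pgi_binned(np.zeros((4, 1, 1, 4, 10)), tiny_layout)
        sm = samplewise_stat(b, intercept_regressor(b.participants))
        assert form_clusters(sm, tiny_adjacency, 0.025, 1) == []
        assert form_clusters(sm, tiny_adjacency, 0.025, -1) == []

    def test_single_suprathreshold_sample(self, tiny_layout, tiny_adjacency):
        # exact zeros elsewhere give t = 0 there; only one live sample
        vals = np.zeros((5, 1, 1, 4, 10))
        vals[:, 0, 0, 2, 4] = 5.0 + 0.1 * np.arange(5)
        b = make_pgi_binned(vals, tiny_layout)
        sm = samplewise_stat(b, intercept_regressor(b.participants))
        clusters = form_clusters(sm, tiny_adjacency, 0.025, 1)
        assert len(clusters) == 1
        assert clusters[0].n_members == 1
        assert clusters[0].mass == pytest.approx(sm.t[2, 4])

    def test_disjoint_blocks_match_flood_fill_oracle(self, tiny_layout,
                                                     tiny_adjacency, rng):
        vals = 0.05 * rng.standard_normal((6, 1, 1, 4, 30))
        vals[:, 0, 0, 0, 3:8] += 4.0      # A25: one block
        vals[:, 0, 0, 2, 20:25] += 4.0    # C13: far channel, later times
        b = make_pgi_binned(vals, tiny_layout)
        sm = samplewise_stat(b, intercept_regressor(b.participants))
        clusters = form_clusters(sm, tiny_adjacency, 0.025, 1)
        thresh = forming_threshold(sm.df, 0.025)
        oracle = oracle_clusters(sm.t, thresh, 1,
                                 tiny_adjacency.neighbor_matrix())
        mine = {frozenset(zip(c.channels.tolist(), c.time_indices.tolist()))
                for c in clusters}
        assert mine == {c["members"] for c in oracle}
        assert len(clusters) >= 2
        masses = sorted(round(c.mass, 9) for c in clusters)
        assert masses == sorted(round(c["mass"], 9) for c in oracle)


class TestPermutationNull:
    def test_constant_zero_data_degenerate_null(self, tiny_layout,
                                                tiny_adjacency):
        b = make_pgi_binned(np.zeros((5, 1, 1, 4, 8)), tiny_layout)
        null = permutation_null(b, intercept_regressor(b.participants),
                                tiny_adjacency, n_perm=200, forming_alpha=0.025,
                                seed=0)
        assert np.all(null[1] == 0.0)
        assert np.all(null[-1] == 0.0)

    def test_seed_reproducibility(self, tiny_layout, tiny_adjacency, rng):
        vals = rng.standard_normal((6, 1, 1, 4, 12))
        b = make_pgi_binned(vals, tiny_layout)
        reg = intercept_regressor(b.participants)
        a = permutation_null(b, reg, tiny_adjacency, n_perm=150,
                             forming_alpha=0.025, seed=42)
        c = permutation_null(b, reg, tiny_adjacency, n_perm=150,
                             forming_alpha=0.025, seed=42)
        assert np.array_equal(a[1], c[1]) and np.array_equal(a[-1], c[-1])

    def test_small_n_perm_warns(self, tiny_layout, tiny_adjacency, rng):
        b = make_pgi_binned(rng.standard_normal((4, 1, 1, 4, 5)), tiny_layout)
        with pytest.warns(UserWarning, match="small"):
            permutation_null(b, intercept_regressor(b.participants),
                             tiny_adjacency, n_perm=50, forming_alpha=0.025,
                             seed=0)

    def test_covariate_shuffle_keeps_bins_with_participant(self, tiny_layout,
                                                           tiny_adjacency,
                                                           rng):
        """Shuffled regressors are column permutations of the bin grid."""
        P, B = 5, 3
        vals = rng.standard_normal((P, B, 1, 4, 6))
        bins = ("partition1", "partition2", "partition3")
        b = make_pgi_binned(vals, tiny_layout, scheme="partitions",
                            bin_labels=bins)
        scores = pd.Series(rng.standard_normal(P), index=b.participants)
        from patternglare.regressors import two_way_regressor, \
            exponential_weights
        reg = two_way_regressor(scores, exponential_weights(3, "decrease", 1.0),
                                bins, "f", "partitions")
        null = permutation_null(b, reg, tiny_adjacency, n_perm=100,
                                forming_alpha=0.025, seed=0)
        assert null[1].shape == (100,)


class TestClusterPvalues:
    def _cluster(self, mass, tail=1):
        from patternglare.mua import ClusterResult
        return ClusterResult(tail=tail, channels=np.array([0]),
                             time_indices=np.array([0]), mass=mass)

    def test_observed_above_all_permutations(self):
        null = {1: np.zeros(9999), -1: np.zeros(9999)}
        c = cluster_pvalues([self._cluster(50.0)], null)[0]
        assert c.p_value == pytest.approx(1.0 / 10_000)

    def test_observed_below_all_permutations(self):
        null = {1: np.full(499, 100.0), -1: np.zeros(499)}
        c = cluster_pvalues([self._cluster(1.0)], null)[0]
        assert c.p_value == 1.0

    def test_negative_tail_uses_own_null(self):
        null = {1: np.full(99, 100.0), -1: np.zeros(99)}
        c = cluster_pvalues([self._cluster(-5.0, tail=-1)], null)[0]
        assert c.p_value == pytest.approx(1.0 / 100)


class TestEffectSizes:
    def _map(self, tval, tiny_layout):
        from patternglare.mua import StatMap
        t = np.zeros((4, 3))
        t[1, 1] = tval
        return StatMap(t, df=33, n_obs=34, times=np.arange(3.0),
                       ch_names=tiny_layout.names, regressor_name="x")

    def _cluster(self):
        from patternglare.mua import ClusterResult
        return ClusterResult(tail=1, channels=np.array([1]),
                             time_indices=np.array([1]), mass=1.0)

    def test_zero_t_zero_effects(self, tiny_layout):
        r, d1, d2 = effect_sizes(self._map(0.0, tiny_layout), self._cluster(),
                                 34, 33)
        assert (r, d1, d2) == (0.0, 0.0, 0.0)

    def test_t_equal_df_algebra(self, tiny_layout):
        df = 33
        r, _, _ = effect_sizes(self._map(float(df), tiny_layout),
                               self._cluster(), 34, df)
        assert r == pytest.approx(np.sqrt(df / (df + 1)))

    def test_one_sample_d_at_table_scale(self, tiny_layout):
        # n = 34 and t = 15.1 correspond to d = t / sqrt(n) ~ 2.59
        _, d1, _ = effect_sizes(self._map(15.1, tiny_layout), self._cluster(),
                                34, 33)
        assert d1 == pytest.approx(15.1 / np.sqrt(34))
        assert d1 == pytest.approx(2.59, abs=0.01)

    def test_invalid_df(self, tiny_layout):
        with pytest.raises(ValueError):
            effect_sizes(self._map(1.0, tiny_layout), self._cluster(), 34, 0)


class TestPeakElectrode:
    def _cluster(self, chans, times):
        from patternglare.mua import ClusterResult
        return ClusterResult(tail=1, channels=np.array(chans),
                             time_indices=np.array(times), mass=1.0)

    def _map(self, t, tiny_layout):
        from patternglare.mua import StatMap
        return StatMap(t, df=5, n_obs=6, times=np.arange(t.shape[1], dtype=float),
                       ch_names=tiny_layout.names, regressor_name="x")

    def test_single_channel_cluster(self, tiny_layout):
        t = np.ones((4, 5))
        c = self._cluster([2, 2], [0, 1])
        assert select_peak_electrode(c, self._map(t, tiny_layout)) == \
            tiny_layout.names[2]

    def test_most_member_timepoints_wins(self, tiny_layout):
        t = np.ones((4, 20))
        c = self._cluster([0] * 10 + [1] * 3, list(range(10)) + [0, 1, 2])
        assert select_peak_electrode(c, self._map(t, tiny_layout)) == \
            tiny_layout.names[0]

    def test_tie_broken_by_summed_t(self, tiny_layout):
        t = np.ones((4, 5))
        t[1, :] = 3.0
        c = self._cluster([0, 0, 1, 1], [0, 1, 0, 1])
        assert select_peak_electrode(c, self._map(t, tiny_layout)) == \
            tiny_layout.names[1]


class TestRunMua:
    def _binned(self, rng, effect=0.0, P=8, T=40):
        lay = subset_layout(DEFAULT_4)
        vals = rng.standard_normal((P, 1, 1, 4, T))
        vals[:, 0, 0, 1, 10:30] += effect
        return make_pgi_binned(vals, lay), build_adjacency(lay, 1.2)

    def test_affine_rescaling_of_regressor_is_invariant(self, rng):
        b, adj = self._binned(rng)
        scores = pd.Series(rng.standard_normal(8), index=b.participants)
        r1 = factor_regressor(scores, "f")
        r2 = factor_regressor(scores * 17.0, "f")
        a = run_mua(b, {"f": r1}, adj, window=(0.5, 1.2), n_perm=150, seed=5)
        c = run_mua(b, {"f": r2}, adj, window=(0.5, 1.2), n_perm=150, seed=5)
        assert np.allclose(a["f"].stat_map.t, c["f"].stat_map.t, atol=1e-9)
        pa = [(x.tail, x.p_value, round(x.mass, 6)) for x in a["f"].clusters]
        pc = [(x.tail, x.p_value, round(x.mass, 6)) for x in c["f"].clusters]
        assert pa == pc

    def test_raising_forming_threshold_shrinks_clusters(self, rng):
        b, adj = self._binned(rng, effect=1.5)
        reg = intercept_regressor(b.participants)
        sm = samplewise_stat(b.restrict_window((0.5, 1.2)), reg)
        loose = form_clusters(sm, adj, 0.05, 1)
        strict = form_clusters(sm, adj, 0.01, 1)
        loose_members = set().union(*[
            set(zip(c.channels.tolist(), c.time_indices.tolist()))
            for c in loose]) if loose else set()
        strict_members = set().union(*[
            set(zip(c.channels.tolist(), c.time_indices.tolist()))
            for c in strict]) if strict else set()
        assert strict_members <= loose_members

    def test_fixed_seed_reproduces_results_bit_for_bit(self, rng):
        b, adj = self._binned(rng, effect=1.0)
        reg = intercept_regressor(b.participants)
        a = run_mua(b, {"i": reg}, adj, window=(0.5, 1.2), n_perm=200, seed=9)
        c = run_mua(b, {"i": reg}, adj, window=(0.5, 1.2), n_perm=200, seed=9)
        for x, y in zip(a["i"].clusters, c["i"].clusters):
            assert x.p_value == y.p_value and x.mass == y.mass
            assert np.array_equal(x.channels, y.channels)
            assert x.peak_channel == y.peak_channel
            assert x.peak_time == y.peak_time

    def test_empty_analysis_window_rejected(self, rng):
        b, adj = self._binned(rng)
        with pytest.raises(ValueError, match="window"):
            run_mua(b, {"i": intercept_regressor(b.participants)}, adj,
                    window=(9.0, 10.0), n_perm=100, seed=0)

    def test_missing_cells_rejected(self, rng):
        b, adj = self._binned(rng)
        b.values[0, 0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            run_mua(b, {"i": intercept_regressor(b.participants)}, adj,
                    window=(0.5, 1.2), n_perm=100, seed=0)


class TestAgainstMne:
    """The cluster stage cross-checked against an established engine."""

    def test_t_map_and_cluster_formation_match(self, rng):
        mne = pytest.importorskip("mne")
        mne.set_log_level("ERROR")
        lay = subset_layout(DEFAULT_16)
        adj = build_adjacency(lay, 0.45)
        n, C, T = 9, 16, 25
        vals = rng.standard_normal((n, 1, C, T))
        vals[:, 0, 8:12, 5:15] += 0.9
        b = make_pgi_binned(vals, lay)
        sm = samplewise_stat(b, intercept_regressor(b.participants))
        thresh = forming_threshold(sm.df, 0.025)
        mine = form_clusters(sm, adj, 0.025, 1) \
            + form_clusters(sm, adj, 0.025, -1)

        X = np.transpose(vals[:, 0], (0, 2, 1))      # obs x time x channel
        T_obs, clusters, _, _ = mne.stats.spatio_temporal_cluster_1samp_test(
            X, threshold=thresh, adjacency=sparse.coo_matrix(
                adj.neighbor_matrix()), n_permutations=64, tail=0, t_power=1,
            seed=1, out_type="indices", verbose="ERROR")
        assert np.abs(T_obs.T - sm.t).max() < 1e-10
        theirs = set()
        for tidx, cidx in clusters:
            theirs.add((frozenset(zip(cidx.tolist(), tidx.tolist())),
                        round(float(T_obs[tidx, cidx].sum()), 6)))
        ours = {(frozenset(zip(c.channels.tolist(), c.time_indices.tolist())),
                 round(c.mass, 6)) for c in mine}
        assert ours == theirs
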