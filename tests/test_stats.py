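"""Sensor adjacency, paired t maps, clustering, and permutation inference."""

import numpy as np
import pytest

import hypercouple as hc
from hypercouple.errors import DataError
from hypercouple.stats import _max_cluster_stat, find_clusters
from hypercouple.synth import SensorLayout

from conftest import make_tfr


def square_layout():
    """Four electrodes at the corners of a small square on the upper sphere."""
    pts = np.array([
        [-0.3, -0.3, 1.0],
        [0.3, -0.3, 1.0],
        [-0.3, 0.3, 1.0],
        [0.3, 0.3, 1.0],
    ])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return SensorLayout(labels=("a", "b", "c", "d"), positions=pts)


def bfs_cluster_oracle(tmap, threshold, neighbor_sets):
    """Independent BFS over the full point graph; returns frozensets of points."""
    n_ch, n_t = tmap.shape
    out = []
    for sign in (1, -1):
        supra = {(c, t) for c in range(n_ch) for t in range(n_t)
                 if sign * tmap[c, t] > threshold}
        seen = set()
        for start in sorted(supra):
            if start in seen:
                continue
            comp, queue = set(), [start]
            seen.add(start)
            while queue:
                c, t = queue.pop(0)
                comp.add((c, t))
                for cand in [(c, t - 1), (c, t + 1)] + \
                        [(nb, t) for nb in neighbor_sets[c]]:
                    if cand in supra and cand not in seen:
                        seen.add(cand)
                        queue.append(cand)
            if len({c for c, _ in comp}) >= 2:
                out.append(frozenset(comp))
    return set(out)


class TestAdjacency:
    def test_unit_square_triangulation(self):
        adj = hc.build_neighbors(square_layout())
        n_edges = adj.matrix.sum() // 2
        assert n_edges == 5  # 4 sides + 1 diagonal from the triangulation
        degrees = adj.matrix.sum(axis=1)
        assert sorted(degrees) == [2, 2, 3, 3]

    def test_montage_properties(self, adjacency):
        assert "FC2" in adjacency.neighbors("Fz")
        assert np.array_equal(adjacency.matrix, adjacency.matrix.T)
        assert not adjacency.matrix.diagonal().any()
        assert (adjacency.matrix.sum(axis=1) >= 2).all()

    def test_single_electrode_empty(self):
        layout = SensorLayout(labels=("x",), positions=np.array([[0.0, 0.0, 1.0]]))
        adj = hc.build_neighbors(layout)
        assert adj.matrix.sum() == 0

    def test_collinear_fallback_warns(self):
        pts = np.column_stack([np.linspace(-0.5, 0.5, 5),
                               np.zeros(5), np.ones(5)])
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        layout = SensorLayout(labels=tuple("abcde"), positions=pts)
        with pytest.warns(UserWarning, match="degenerate"):
            adj = hc.build_neighbors(layout)
        assert np.array_equal(adj.matrix, adj.matrix.T)
        assert adj.matrix.sum() > 0


class TestDependentTMap:
    def test_equal_conditions_zero(self):
        a = np.random.default_rng(0).standard_normal((6, 3, 4))
        out = hc.dependent_t_map(a, a.copy())
        assert np.allclose(out.t, 0.0)
        assert out.df == 5

    def test_degenerate_point_flagged_infinite(self):
        a = np.zeros((4, 1, 1))
        b = np.zeros((4, 1, 1))
        a[:, 0, 0] = [1.0, 1.0, 1.0, 1.0]
        out = hc.dependent_t_map(a, b)
        assert np.isposinf(out.t[0, 0])
        assert out.degenerate[0, 0]

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((10, 2, 3))
        b = rng.standard_normal((10, 2, 3))
        out = hc.dependent_t_map(a, b)
        d = a - b
        for ch in range(2):
            for t in range(3):
                dd = d[:, ch, t]
                expect = dd.mean() / (dd.std(ddof=1) / np.sqrt(len(dd)))
                assert out.t[ch, t] == pytest.approx(expect, abs=1e-10)


class TestFindClusters:
    def test_no_supra_threshold_points(self, adjacency):
        tmap = np.zeros((32, 5))
        assert find_clusters(tmap, 2.0, adjacency) == []

    def test_block_cluster_maxsum(self, adjacency):
        """A 2-neighboring-channel x 3-time block of t=5 sums to 30."""
        labels = adjacency.labels
        i, j = labels.index("Fz"), labels.index("FC2")
        tmap = np.zeros((32, 5))
        tmap[[i, j], 1:4] = 5.0
        clusters = find_clusters(tmap, 2.0, adjacency)
        assert len(clusters) == 1
        assert clusters[0].stat == pytest.approx(30.0)
        assert clusters[0].sign == 1
        assert set(clusters[0].channel_indices()) == {i, j}

    def test_single_channel_footprint_discarded(self, adjacency):
        tmap = np.zeros((32, 5))
        tmap[0, :] = 5.0  # one channel only
        assert find_clusters(tmap, 2.0, adjacency) == []

    def test_matches_bfs_oracle(self, adjacency):
        rng = np.random.default_rng(3)
        nb_sets = [set(np.flatnonzero(row)) for row in adjacency.matrix]
        for _ in range(10):
            tmap = rng.standard_normal((32, 8)) * 2.0
            got = {
                frozenset(map(tuple, np.argwhere(c.mask)))
                for c in find_clusters(tmap, 2.0, adjacency)
            }
            expect = bfs_cluster_oracle(tmap, 2.0, nb_sets)
            assert got == expect
            best = max((abs(sum(tmap[c, t] for c, t in comp)) for comp in expect),
                       default=0.0)
            assert _max_cluster_stat(tmap, 2.0, adjacency.neighbor_lists()) \
                == pytest.approx(best)


class TestPermutationTest:
    def test_equal_conditions_empty(self, adjacency):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((8, 32, 4))
        res = hc.cluster_permutation_test(a, a.copy(), adjacency, n_perm=100, seed=1)
        assert res.clusters == []

    def test_planted_effect_reaches_p_floor(self, adjacency):
        """A large offset in every unit attains the minimal p = 1/(n_perm+1)."""
        rng = np.random.default_rng(1)
        b = rng.standard_normal((20, 32, 8))
        a = b.copy()
        labels = adjacency.labels
        chans = [labels.index(c) for c in ("Fz", "FC1", "FC2")]
        a[:, chans, 2:6] += 10.0
        res = hc.cluster_permutation_test(a, b, adjacency, n_perm=500, seed=2)
        assert res.clusters
        assert res.clusters[0].p == pytest.approx(1 / 501)

    def test_exchangeability(self, adjacency):
        """Relabeling units leaves cluster statistics and p-values unchanged."""
        rng = np.random.default_rng(2)
        b = rng.standard_normal((12, 32, 6))
        a = b + 0.8 * rng.standard_normal((12, 32, 6))
        a[:, :5, :] += 1.0
        res1 = hc.cluster_permutation_test(a, b, adjacency, n_perm=200, seed=3)
        perm = rng.permutation(12)
        res2 = hc.cluster_permutation_test(a[perm], b[perm], adjacency,
                                           n_perm=200, seed=3)
        stats1 = sorted(round(c.stat, 6) for c in res1.clusters)
        stats2 = sorted(round(c.stat, 6) for c in res2.clusters)
        assert stats1 == stats2
        # sign-flip draws are unit-indexed, so the null (and hence p) is
        # identical in distribution and identical here given the same seed
        assert sorted(c.p for c in res1.clusters) == sorted(c.p for c in res2.clusters)

    def test_sign_coherence(self, adjacency):
        """Swapping condition order negates t and swaps cluster signs."""
        rng = np.random.default_rng(4)
        b = rng.standard_normal((10, 32, 6))
        a = b + 0.5 * rng.standard_normal((10, 32, 6))
        a[:, :6, 1:4] += 1.5
        res_ab = hc.cluster_permutation_test(a, b, adjacency, n_perm=200, seed=5)
        res_ba = hc.cluster_permutation_test(b, a, adjacency, n_perm=200, seed=5)
        key = lambda c: (round(abs(c.stat), 6), c.mask.tobytes())
        ab = sorted(((k := key(c)), c.sign, c.p) for c in res_ab.clusters)
        ba = sorted(((k := key(c)), -c.sign, c.p) for c in res_ba.clusters)
        assert ab == ba

    def test_exact_enumeration_small_n(self, adjacency):
        rng = np.random.default_rng(6)
        b = rng.standard_normal((6, 32, 4))
        a = b + rng.standard_normal((6, 32, 4))
        with pytest.warns(UserWarning, match="permutation space"):
            res = hc.cluster_permutation_test(a[:4], b[:4], adjacency,
                                              n_perm=100, seed=0)
        assert res.exact
        assert res.n_perm == 16

    def test_monotone_power(self, adjacency):
        """Detection rate never decreases with effect size (3 sizes, fixed seeds)."""
        labels = adjacency.labels
        chans = [labels.index(c) for c in ("Fz", "FC1", "FC2")]
        rates = []
        for effect in (0.0, 0.6, 2.0):
            hits = 0
            for seed in range(8):
                rng = np.random.default_rng(1000 + seed)
                b = rng.standard_normal((12, 32, 6))
                a = b + rng.standard_normal((12, 32, 6))
                a[:, chans, 2:5] += effect
                res = hc.cluster_permutation_test(a, b, adjacency,
                                                  n_perm=200, seed=seed)
                hits += res.min_p() <= 0.05
            rates.append(hits / 8)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] == 1.0

    def test_n_perm_floor(self, adjacency):
        a = np.random.default_rng(0).standard_normal((8, 32, 4))
        with pytest.raises(DataError):
            hc.cluster_permutation_test(a, a, adjacency, n_perm=50)


class TestBandWindowContrast:
    def test_constant_band_average_reduces_to_mean(self, adjacency):
        """Band averaging a constant-power map returns that constant."""
        rng = np.random.default_rng(0)
        maps_a, maps_b = [], []
        for _ in range(6):
            p = np.full((5, 32, 4, 6), 2.0) + 0.01 * rng.standard_normal((5, 32, 4, 6))
            maps_a.append(make_tfr(p, freqs=[4, 5, 6, 7],
                                   times=np.arange(6) * 0.1,
                                   labels=adjacency.labels))
            maps_b.append(make_tfr(np.full((5, 32, 4, 6), 2.0),
                                   freqs=[4, 5, 6, 7], times=np.arange(6) * 0.1,
                                   labels=adjacency.labels))
        band = hc.BANDS["theta"]
        res = hc.band_window_contrast(maps_a, maps_b, band, adjacency,
                                      window=(0.0, 0.4), n_perm=100, seed=0)
        assert res.band == "theta"
        assert res.n_units == 6

    def test_planted_coupling_difference_detected(self, adjacency):
        """Fisher-Z maps with a fronto-central offset yield a positive cluster."""
        rng = np.random.default_rng(1)
        labels = adjacency.labels
        chans = [labels.index(c) for c in ("Fz", "FC1", "FC2", "Cz")]
        maps_a, maps_b = [], []
        for _ in range(12):
            za = 0.2 * rng.standard_normal((32, 4, 6))
            zb = 0.2 * rng.standard_normal((32, 4, 6))
            za[chans, :, 1:4] += 0.6
            zb[chans, :, 1:4] -= 0.6
            common = dict(freqs=np.array([4.0, 5, 6, 7]),
                          times=np.arange(6) * 0.1,
                          channel_labels=labels, n_trials=40)
            maps_a.append(hc.CouplingMap(z=za, rho=np.tanh(za), **common))
            maps_b.append(hc.CouplingMap(z=zb, rho=np.tanh(zb), **common))
        res = hc.band_window_contrast(maps_a, maps_b, hc.BANDS["theta"], adjacency,
                                      window=(0.0, 0.5), n_perm=200, seed=2)
        assert res.clusters
        top = res.clusters[0]
        assert top.sign == 1
        assert top.p <= 0.05
        d = res.to_dict()
        assert d["clusters"][0]["channels"]
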