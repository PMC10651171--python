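"""Cluster-permutation statistics against closed forms and brute force."""

import numpy as np
import pytest
from scipy.stats import norm

from herpipeline.cluster import (
    ZMap,
    combined_cluster_effect,
    combined_pair_effect,
    find_candidate_clusters,
    permutation_test,
    zmap_unpaired,
)
from herpipeline.core_io import SensorLayout, build_neighbor_graph
from herpipeline.sim import grid_layout, simulate_effect_maps

from oracles import cluster_mc_p_naive, ranksum_z_naive


def mutual_layout(n=6):
    """n channels all within 4 cm of each other."""
    pos = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0], [1, 1, 1], [1, 0, 2]],
                   dtype=float)[:n]
    return SensorLayout([f"C{i}" for i in range(n)], pos)


class TestZmap:
    def test_closed_form_example(self):
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        b = np.array([4.0, 5.0, 6.0]).reshape(3, 1, 1)
        zm = zmap_unpaired(a, b)
        assert zm.z[0, 0] == pytest.approx(-1.9640, abs=1e-4)

    def test_identical_groups_zero(self, rng):
        a = np.tile(rng.normal(0, 1, (1, 4, 6)), (3, 1, 1))
        zm = zmap_unpaired(a, a.copy())
        assert np.allclose(zm.z, 0.0)

    def test_antisymmetry(self, rng):
        a = rng.normal(0, 1, (4, 3, 5))
        b = rng.normal(0.5, 1, (5, 3, 5))
        assert np.allclose(zmap_unpaired(a, b).z, -zmap_unpaired(b, a).z)

    def test_matches_naive_with_ties(self, rng):
        a = rng.integers(0, 4, (5, 2, 3)).astype(float)
        b = rng.integers(0, 4, (6, 2, 3)).astype(float)
        zm = zmap_unpaired(a, b)
        for c in range(2):
            for t in range(3):
                assert zm.z[c, t] == pytest.approx(
                    ranksum_z_naive(a[:, c, t], b[:, c, t]), abs=1e-12
                )

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            zmap_unpaired(rng.normal(0, 1, (3, 2, 4)), rng.normal(0, 1, (3, 2, 5)))


class TestCandidateClusters:
    def _zmap(self, z):
        z = np.asarray(z, dtype=float)
        return ZMap(z=z, p=2 * norm.sf(np.abs(z)))

    def test_empty_mask_no_clusters(self):
        g = build_neighbor_graph(mutual_layout())
        zm = self._zmap(np.zeros((6, 10)))
        assert find_candidate_clusters(zm, g) == []

    def test_three_channel_patch_dropped(self):
        g = build_neighbor_graph(mutual_layout())
        z = np.zeros((6, 20))
        z[:3, :] = 3.0  # persists 20 samples but only 3 channels
        assert find_candidate_clusters(self._zmap(z), g) == []

    def test_wrapping_requires_shared_channel(self):
        # 10 channels in two mutually-adjacent pentads, bridged by channel 4
        pos = np.zeros((10, 3))
        pos[:5, 0] = [0, 1, 2, 3, 4]
        pos[5:, 0] = [4, 5, 6, 7, 8]
        pos[5:, 1] = 3.0
        lay = SensorLayout([f"C{i}" for i in range(10)], pos)
        g = build_neighbor_graph(lay, 4.5)
        z = np.zeros((10, 2))
        z[:5, 0] = 3.0     # pentad A at t=0
        z[4:9, 1] = 3.0    # pentad sharing channel 4 at t=1
        clusters = find_candidate_clusters(self._zmap(z), g)
        assert len(clusters) == 1  # wrapped into one cluster
        z2 = np.zeros((10, 2))
        z2[:5, 0] = 3.0
        z2[5:, 1] = 3.0    # no shared channel
        clusters2 = find_candidate_clusters(self._zmap(z2), g)
        assert len(clusters2) == 2

    def test_signs_clustered_separately(self):
        g = build_neighbor_graph(mutual_layout())
        z = np.zeros((6, 4))
        z[:, 1] = 3.0
        z[:, 2] = -3.0
        clusters = find_candidate_clusters(self._zmap(z), g)
        assert sorted(c.sign for c in clusters) == [-1, 1]


class TestPermutationTest:
    def test_exhaustive_matches_brute_force_oracle(self, rng):
        """4v4 subjects, 6 mutually neighbouring channels x 5 samples:
        exhaustive Monte Carlo p equals an independently coded oracle."""
        lay = mutual_layout()
        g = build_neighbor_graph(lay)
        a = rng.normal(1.2, 1.0, (4, 6, 5))
        b = rng.normal(0.0, 1.0, (4, 6, 5))
        res = permutation_test(a, b, g, n_partitions=10_000, seed=0)
        assert res.exhaustive and res.n_partitions == 70
        adjacency = [set(range(6)) - {i} for i in range(6)]
        obs, mc_ps, perm_stats = cluster_mc_p_naive(a, b, adjacency)
        assert len(res.clusters) == len(obs)
        impl = sorted((c.sign, tuple(c.members), c.stat, c.mc_p) for c in res.clusters)
        orac = sorted(
            (s, tuple(m), st, p) for ((s, m, st), p) in zip(obs, mc_ps)
        )
        for (s1, m1, st1, p1), (s2, m2, st2, p2) in zip(impl, orac):
            assert s1 == s2 and m1 == m2
            assert st1 == pytest.approx(st2, abs=1e-10)
            assert p1 == pytest.approx(p2, abs=1e-12)
        assert np.allclose(np.sort(res.perm_distribution), np.sort(perm_stats))

    def test_positive_shift_strengthens_positive_cluster(self, rng):
        lay = grid_layout(4, 4)
        g = build_neighbor_graph(lay)
        a, b = simulate_effect_maps(8, 8, lay, 20, seed=3, shift_a=1.0)
        res1 = permutation_test(a, b, g, n_partitions=400, seed=1)
        res2 = permutation_test(a + 1.0, b, g, n_partitions=400, seed=1)
        pos1 = [c for c in res1.clusters if c.sign > 0]
        pos2 = [c for c in res2.clusters if c.sign > 0]
        assert pos1 and pos2
        assert pos2[0].stat >= pos1[0].stat
        assert pos2[0].mc_p <= pos1[0].mc_p

    def test_subject_order_within_group_irrelevant(self, rng):
        # exhaustive regime: C(8,4)=70 partitions, so the Monte Carlo p
        # is exact and must ignore subject ordering entirely
        lay = grid_layout(4, 4)
        g = build_neighbor_graph(lay)
        a, b = simulate_effect_maps(4, 4, lay, 15, seed=4, shift_a=1.2)
        r1 = permutation_test(a, b, g, n_partitions=300, seed=2)
        r2 = permutation_test(a[::-1], b, g, n_partitions=300, seed=2)
        assert np.allclose(r1.zmap.z, r2.zmap.z)
        assert [c.mc_p for c in r1.clusters] == [c.mc_p for c in r2.clusters]

    def test_too_few_partitions_rejected(self, rng):
        lay = grid_layout(4, 4)
        g = build_neighbor_graph(lay)
        a, b = simulate_effect_maps(4, 4, lay, 5, seed=5)
        with pytest.raises(ValueError):
            permutation_test(a, b, g, n_partitions=0, seed=0)


class TestCombinedEffect:
    def _cluster(self, members):
        from herpipeline.cluster import Cluster

        return Cluster(members=members, sign=1, stat=3.0, latency_ms=(0.0, 4.0))

    def test_constant_map_gives_constant(self):
        maps = np.full((3, 4, 5), 2.5)
        cl = self._cluster([(0, 0), (1, 1), (2, 2)])
        assert np.allclose(combined_cluster_effect(maps, cl), 2.5)

    def test_half_and_half_average(self):
        maps = np.zeros((1, 2, 2))
        maps[0, 0, :] = 2.0
        cl = self._cluster([(0, 0), (0, 1), (1, 0), (1, 1)])
        assert combined_cluster_effect(maps, cl)[0] == pytest.approx(1.0)

    def test_antisymmetric_subjects(self, rng):
        m = rng.normal(0, 1, (4, 6))
        maps = np.stack([m, -m])
        cl = self._cluster([(0, 0), (2, 3), (3, 5)])
        vals = combined_cluster_effect(maps, cl)
        assert vals[0] == pytest.approx(-vals[1])

    def test_pair_effect_positive_minus_negative(self, rng):
        maps = rng.normal(0, 1, (3, 4, 5))
        pos = self._cluster([(0, 0), (1, 1)])
        neg = self._cluster([(2, 2), (3, 3)])
        both = combined_pair_effect(maps, pos, neg)
        expect = combined_cluster_effect(maps, pos) - combined_cluster_effect(maps, neg)
        assert np.allclose(both, expect)
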