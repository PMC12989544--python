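"""Normal estimation, adaptive eps, constrained DBSCAN, merging, counting."""

import numpy as np
import pytest
from sklearn.cluster import DBSCAN

from teabud3d import (
    BudCluster, ClusteringConfig, SceneSpec, SemanticPointCloud, adaptive_eps,
    count_buds, dbscan_cluster, dsc_filter, estimate_normals, generate_tree,
    merge_clusters, volume_filter,
)
from teabud3d.clustering import hull_volume
from teabud3d.errors import ConfigurationError, InsufficientPointsError

from conftest import random_cloud


def cloud_of(positions):
    return SemanticPointCloud(positions=np.asarray(positions, dtype=float))


class TestEstimateNormals:
    def test_planar_clouds(self, rng):
        xy = rng.uniform(-1, 1, (200, 2))
        flat = cloud_of(np.column_stack([xy, np.zeros(200)]))
        normals = estimate_normals(flat, k=8)
        assert np.allclose(normals, [0, 0, 1], atol=1e-9)
        # vertical plane x = 0: sign fixed to +x
        wall = cloud_of(np.column_stack([np.zeros(200), xy]))
        normals = estimate_normals(wall, k=8)
        assert np.allclose(normals, [1, 0, 0], atol=1e-9)

    def test_sphere_normals_radial(self, rng):
        v = rng.normal(size=(2000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v + rng.normal(0, 0.01, v.shape)  # radius 1, 1% noise
        normals = estimate_normals(cloud_of(pts), k=12)
        radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(np.abs(np.sum(normals * radial, axis=1)), 0, 1)))
        assert np.percentile(ang, 99) < 15.0

    def test_too_few_points(self, rng):
        with pytest.raises(InsufficientPointsError):
            estimate_normals(cloud_of(rng.normal(size=(5, 3))), k=8)


class TestAdaptiveEps:
    def test_unit_chain(self):
        chain = cloud_of(np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)]))
        assert adaptive_eps(chain, k=1) == pytest.approx(1.5)

    def test_scale_equivariance(self, rng):
        c = random_cloud(rng, 300)
        big = cloud_of(c.positions * 10)
        assert adaptive_eps(big, k=5) == pytest.approx(10 * adaptive_eps(c, k=5))

    def test_matches_brute_force_median(self, rng):
        c = random_cloud(rng, 150)
        d = np.linalg.norm(c.positions[:, None] - c.positions[None, :], axis=2)
        kth = np.sort(d, axis=1)[:, 4]  # 4th NN excluding self
        assert adaptive_eps(c, k=4, factor=1.5) == pytest.approx(1.5 * np.median(kth))


class TestDbscan:
    def test_vacuous_clamp_equals_reference_dbscan(self, rng):
        for _ in range(10):
            c = random_cloud(rng, 250, scale=2.0)
            cfg = ClusteringConfig(eps=0.45, min_pts=5, clamp_angle_deg=180.0)
            ours = dbscan_cluster(c, cfg)
            ref = DBSCAN(eps=0.45, min_samples=5).fit(c.positions).labels_
            assert np.array_equal(ours, ref)

    def test_parallel_vs_perpendicular_planes(self, rng):
        xy = rng.uniform(0, 4, (600, 2))
        lower = np.column_stack([xy, np.zeros(600)])
        upper = np.column_stack([xy, np.full(600, 0.5)])
        both = cloud_of(np.vstack([lower, upper]))
        normals = estimate_normals(both, k=8)
        cfg = ClusteringConfig(eps=1.0, min_pts=4, clamp_angle_deg=180.0)
        labels = dbscan_cluster(both, cfg, normals)
        assert len(set(labels.tolist()) - {-1}) == 1
        # parallel planes share normals: still one cluster at 15 degrees
        cfg15 = ClusteringConfig(eps=1.0, min_pts=4, clamp_angle_deg=15.0)
        labels = dbscan_cluster(both, cfg15, normals)
        assert len(set(labels.tolist()) - {-1}) == 1
        # perpendicular planes meeting at an edge: two clusters at 15 degrees
        uv = rng.uniform(0, 4, (600, 2))
        wall = np.column_stack([uv[:, 0], np.zeros(600), uv[:, 1] + 0.01])
        floor_wall = cloud_of(np.vstack([lower, wall]))
        normals = estimate_normals(floor_wall, k=8)
        labels15 = dbscan_cluster(floor_wall, ClusteringConfig(eps=0.6, min_pts=4,
                                                               clamp_angle_deg=15.0), normals)
        labels180 = dbscan_cluster(floor_wall, ClusteringConfig(eps=0.6, min_pts=4,
                                                                clamp_angle_deg=180.0), normals)
        assert len(set(labels180.tolist()) - {-1}) == 1
        assert len(set(labels15.tolist()) - {-1}) == 2

    def test_requires_normals_when_constrained(self, rng):
        c = random_cloud(rng, 50)
        with pytest.raises(ConfigurationError):
            dbscan_cluster(c, ClusteringConfig(eps=0.5, clamp_angle_deg=15.0), None)


class TestMergeClusters:
    def _cluster_at(self, center, positions_list, start):
        idx = np.arange(start, start + len(positions_list))
        return BudCluster(point_indices=idx, centroid=np.asarray(center, dtype=float),
                          volume=1.0, mean_normal=np.array([0.0, 0.0, 1.0]))

    def test_merge_below_radius_strict_boundary(self):
        a = self._cluster_at([0, 0, 0], range(5), 0)
        b = self._cluster_at([0.9, 0, 0], range(5), 5)
        assert len(merge_clusters([a, b], avg_bud_radius=1.0)) == 1
        c = self._cluster_at([1.0, 0, 0], range(5), 5)
        assert len(merge_clusters([a, c], avg_bud_radius=1.0)) == 2  # strict <

    def test_transitive_chain(self):
        a = self._cluster_at([0, 0, 0], range(3), 0)
        b = self._cluster_at([0.8, 0, 0], range(3), 3)
        c = self._cluster_at([1.6, 0, 0], range(3), 6)
        merged = merge_clusters([a, b, c], avg_bud_radius=1.0)
        assert len(merged) == 1
        assert np.array_equal(np.sort(merged[0].point_indices), np.arange(9))

    def test_idempotent_and_order_independent(self, rng):
        cents = rng.uniform(0, 3, (8, 3))
        clusters = [self._cluster_at(c, range(2), 2 * i) for i, c in enumerate(cents)]
        merged = merge_clusters(clusters, avg_bud_radius=0.8)
        again = merge_clusters(merged, avg_bud_radius=0.8)
        part = sorted(tuple(np.sort(c.point_indices)) for c in merged)
        assert sorted(tuple(np.sort(c.point_indices)) for c in again) == part
        perm = [clusters[i] for i in rng.permutation(8)]
        merged_p = merge_clusters(perm, avg_bud_radius=0.8)
        assert sorted(tuple(np.sort(c.point_indices)) for c in merged_p) == part


class TestVolumeFilter:
    def _cube_cluster(self, scale, start, rng):
        pts = rng.uniform(0, scale, (40, 3))
        pos = np.vstack([pts])
        return BudCluster.from_points(np.arange(40), pos), pos

    def test_hull_volume_oracle_cubes(self, rng):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
        assert hull_volume(corners) == pytest.approx(1.0)
        assert hull_volume(corners[:3]) == 0.0  # degenerate

    def test_small_cluster_removed(self, rng):
        big = [BudCluster(point_indices=np.arange(4), centroid=np.zeros(3),
                          volume=1.0, mean_normal=np.array([0, 0, 1.0]))
               for _ in range(4)]
        tiny = BudCluster(point_indices=np.arange(4), centroid=np.zeros(3),
                          volume=0.01, mean_normal=np.array([0, 0, 1.0]))
        kept = volume_filter(big + [tiny], min_volume_fraction=0.1)
        assert len(kept) == 4
        assert all(c.volume == 1.0 for c in kept)

    def test_identical_and_single_clusters_kept(self):
        c = BudCluster(point_indices=np.arange(4), centroid=np.zeros(3),
                       volume=0.5, mean_normal=np.array([0, 0, 1.0]))
        assert len(volume_filter([c] * 5, 0.99)) == 5
        assert len(volume_filter([c], 0.5)) == 1
        assert volume_filter([], 0.5) == []


class TestCountBuds:
    def test_clean_scene_recovery(self, clean_scene, clean_bud_cloud):
        spec, _, truth = clean_scene
        count, clusters = count_buds(clean_bud_cloud, ClusteringConfig())
        assert count == truth.bud_count
        # memberships agree with truth up to small boundary loss
        labels = clean_bud_cloud.label
        for c in clusters:
            buds_in = np.unique(labels[c.point_indices])
            assert len(buds_in) == 1

    def test_adjacent_buds_merge_undercount(self):
        # two buds closer than the merge radius collapse into one cluster:
        # the under-counting failure mode of dense bud regions
        spec = SceneSpec(n_buds=5, seed=3, occlusion_dropout=0.0, noise_sd=0.0)
        cloud, truth = generate_tree(spec)
        _, buds = dsc_filter(cloud)
        # translate bud 1 so its centroid nearly coincides with bud 0's
        labels = buds.label
        c0 = buds.positions[labels == 0].mean(axis=0)
        c1 = buds.positions[labels == 1].mean(axis=0)
        shifted = buds.positions.copy()
        shifted[labels == 1] += (c0 - c1) + np.array([0.012, 0.0, 0.0])
        moved = SemanticPointCloud(positions=shifted, density=buds.density,
                                   bud_prob=buds.bud_prob, label=labels)
        count, _ = count_buds(moved, ClusteringConfig())
        assert count == spec.n_buds - 1

    def test_empty_cloud_counts_zero(self):
        empty = SemanticPointCloud(positions=np.zeros((0, 3)))
        assert count_buds(empty, ClusteringConfig()) == (0, [])

    def test_dropout_monotone_trend(self):
        # expected count never rises as occlusion removes points (merge-free
        # scenes); non-strict trend over seeds
        means = []
        for d in (0.0, 0.45, 0.9):
            counts = []
            for seed in range(3):
                spec = SceneSpec(n_buds=5, seed=seed, occlusion_dropout=d,
                                 noise_sd=0.0, foliage_points=0, floater_fraction=0.0)
                cloud, _ = generate_tree(spec)
                _, buds = dsc_filter(cloud)
                counts.append(count_buds(buds, ClusteringConfig())[0])
            means.append(np.mean(counts))
        assert means[0] >= means[-1]
        assert means[0] == 5.0
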