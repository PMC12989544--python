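"""Cloud container, density-gated semantic filtering, outlier filters, PLY I/O."""

import numpy as np
import pytest

from teabud3d import (
    SemanticPointCloud, dsc_filter, radius_outlier_removal, read_ply,
    statistical_outlier_removal, write_ply,
)
from teabud3d.cloud import dsc_masks, radius_outlier_mask
from teabud3d.errors import InsufficientPointsError, InvalidThresholdError, PlyFormatError


def make_cloud(positions, density=None, bud_prob=None):
    return SemanticPointCloud(positions=np.asarray(positions, dtype=float),
                              density=density, bud_prob=bud_prob)


class TestDscFilter:
    def test_density_threshold_is_inclusive(self):
        cloud = make_cloud([[0, 0, 0], [1, 0, 0]],
                           density=[0.44, 0.45], bud_prob=[0.99, 0.99])
        tree, buds = dsc_filter(cloud)
        # 0.44 is below the sigma >= 0.45 gate, 0.45 passes it
        assert len(tree) == 1 and len(buds) == 1
        assert tree.positions[0, 0] == 1.0

    def test_empty_cloud(self):
        tree, buds = dsc_filter(make_cloud(np.zeros((0, 3))))
        assert len(tree) == 0 and len(buds) == 0

    def test_idempotent_and_nested(self, rng):
        n = 500
        cloud = make_cloud(rng.normal(size=(n, 3)), density=rng.uniform(0, 1, n),
                           bud_prob=rng.uniform(0, 1, n))
        tree_mask, bud_mask = dsc_masks(cloud)
        assert np.all(bud_mask <= tree_mask)  # bud subset of tree
        tree, buds = dsc_filter(cloud)
        tree2, buds2 = dsc_filter(tree)
        assert np.array_equal(tree2.positions, tree.positions)
        buds_again = dsc_filter(buds)[1]
        assert np.array_equal(buds_again.positions, buds.positions)

    def test_invalid_thresholds(self):
        cloud = make_cloud([[0, 0, 0]])
        with pytest.raises(InvalidThresholdError):
            dsc_filter(cloud, sigma_min=-0.1)
        with pytest.raises(InvalidThresholdError):
            dsc_filter(cloud, prob_min=1.5)

    def test_floaters_never_survive(self, clean_scene):
        spec, cloud, truth = clean_scene
        bud_idx = np.concatenate(truth.bud_memberships)
        floater_idx = np.flatnonzero((cloud.label == -1) & (cloud.bud_prob >= 0.5))
        assert len(floater_idx) > 0
        _, bud_mask = dsc_masks(cloud)
        assert not bud_mask[floater_idx].any()
        assert bud_mask[bud_idx].all()


class TestRadiusOutlierRemoval:
    def test_isolated_point_removed(self, rng):
        cluster = rng.normal(scale=0.2, size=(500, 3))
        cloud = make_cloud(np.vstack([cluster, [[100.0, 0, 0]]]))
        out = radius_outlier_removal(cloud, radius=1.0, min_neighbors=3)
        assert len(out) == 500
        assert np.abs(out.positions[:, 0]).max() < 50

    def test_min_neighbors_zero_rejected(self):
        with pytest.raises(InvalidThresholdError):
            radius_outlier_removal(make_cloud([[0, 0, 0]]), 1.0, 0)
        with pytest.raises(InvalidThresholdError):
            radius_outlier_removal(make_cloud([[0, 0, 0]]), -1.0, 3)

    @pytest.mark.parametrize("n,radius,min_nb", [(300, 0.5, 3), (200, 0.3, 5)])
    def test_matches_brute_force_oracle(self, rng, n, radius, min_nb):
        pos = rng.uniform(-1, 1, (n, 3))
        cloud = make_cloud(pos)
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        expected = (d <= radius).sum(axis=1) - 1 >= min_nb
        assert np.array_equal(radius_outlier_mask(cloud, radius, min_nb), expected)

    def test_permutation_equivariance(self, rng):
        pos = rng.uniform(-1, 1, (200, 3))
        perm = rng.permutation(200)
        mask = radius_outlier_mask(make_cloud(pos), 0.4, 3)
        mask_p = radius_outlier_mask(make_cloud(pos[perm]), 0.4, 3)
        assert np.array_equal(mask_p, mask[perm])


class TestStatisticalOutlierRemoval:
    def test_grid_with_far_outlier(self):
        g = np.arange(5)
        grid = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T.astype(float)
        cloud = make_cloud(np.vstack([grid, [[30.0, 30.0, 30.0]]]))
        out = statistical_outlier_removal(cloud, k=8, std_ratio=2.0)
        assert len(out) == len(grid)
        assert out.positions.max() <= 4.0

    def test_infinite_ratio_is_identity(self, rng):
        cloud = make_cloud(rng.normal(size=(100, 3)))
        out = statistical_outlier_removal(cloud, k=8, std_ratio=1e12)
        assert len(out) == 100

    def test_too_few_points(self, rng):
        cloud = make_cloud(rng.normal(size=(8, 3)))
        with pytest.raises(InsufficientPointsError):
            statistical_outlier_removal(cloud, k=8, std_ratio=2.0)


class TestPlyIO:
    def _example_cloud(self, rng, n=64):
        return SemanticPointCloud(
            positions=rng.normal(size=(n, 3)).astype(np.float32).astype(np.float64),
            colors=rng.integers(0, 256, (n, 3)).astype(np.float64) / 255.0,
            density=rng.uniform(0, 1, n).astype(np.float32).astype(np.float64),
            bud_prob=rng.uniform(0, 1, n).astype(np.float32).astype(np.float64),
            label=rng.integers(-1, 5, n).astype(np.int32),
            extras={"curvature": rng.uniform(0, 1, n).astype(np.float32)},
        )

    def test_binary_round_trip_bit_exact(self, rng, tmp_path):
        cloud = self._example_cloud(rng)
        path = tmp_path / "c.ply"
        write_ply(cloud, path)
        back = read_ply(path)
        assert np.array_equal(back.positions, cloud.positions)
        assert np.array_equal(back.density, cloud.density)
        assert np.array_equal(back.bud_prob, cloud.bud_prob)
        assert np.array_equal(back.label, cloud.label)
        assert np.array_equal(back.colors, cloud.colors)
        assert np.array_equal(back.extras["curvature"], cloud.extras["curvature"])
        # write determinism: byte-identical files
        write_ply(back, tmp_path / "c2.ply")
        assert (tmp_path / "c.ply").read_bytes() == (tmp_path / "c2.ply").read_bytes()

    def test_ascii_matches_binary(self, rng, tmp_path):
        cloud = self._example_cloud(rng)
        write_ply(cloud, tmp_path / "b.ply", binary=True)
        write_ply(cloud, tmp_path / "a.ply", binary=False)
        b, a = read_ply(tmp_path / "b.ply"), read_ply(tmp_path / "a.ply")
        assert np.allclose(a.positions, b.positions, atol=1e-6)
        assert np.array_equal(a.label, b.label)

    def test_xyz_only_defaults_with_warning(self, tmp_path):
        p = tmp_path / "xyz.ply"
        p.write_bytes(b"ply\nformat ascii 1.0\nelement vertex 2\n"
                      b"property float x\nproperty float y\nproperty float z\n"
                      b"end_header\n0 0 0\n1 2 3\n")
        with pytest.warns(UserWarning):
            cloud = read_ply(p)
        assert np.array_equal(cloud.density, [1.0, 1.0])
        assert np.array_equal(cloud.bud_prob, [0.0, 0.0])
        assert np.array_equal(cloud.label, [-1, -1])

    def test_truncated_body_names_offset(self, rng, tmp_path):
        cloud = self._example_cloud(rng)
        path = tmp_path / "t.ply"
        write_ply(cloud, path)
        data = path.read_bytes()
        path.write_bytes(data[:-10])
        with pytest.raises(PlyFormatError, match="offset"):
            read_ply(path)

    def test_not_a_ply(self, tmp_path):
        p = tmp_path / "x.ply"
        p.write_bytes(b"garbage")
        with pytest.raises(PlyFormatError):
            read_ply(p)
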