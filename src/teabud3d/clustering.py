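"""Bud instance separation and counting on semantic point clouds.

The counting pipeline separates a bud-labeled cloud into per-bud clusters and
counts them:

1. per-point surface normals from the PCA of each point's k nearest neighbors;
2. a neighborhood radius (eps) either fixed or adapted to local point density
   as median k-th-neighbor distance times a factor;
3. DBSCAN in which two points are neighbors only if they are within eps AND
   their normals agree to within a clamp angle (default 15 degrees,
   orientation-insensitive) — the normal-consistency constraint that reduces
   cluster adhesion between adjacent buds;
4. merging of clusters whose centroids are closer than the average bud radius
   (transitive closure), since such fragments belong to one bud;
5. rejection of clusters whose convex-hull volume is far below the median,
   which removes non-bud debris.

The DBSCAN expansion replicates the classic index-ordered algorithm, so with
the constraint disabled (clamp angle 180) its labels coincide with standard
DBSCAN implementations on the same eps/min_pts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cloud import SemanticPointCloud
from .errors import ConfigurationError, InsufficientPointsError

__all__ = [
    "ClusteringConfig", "BudCluster",
    "estimate_normals", "adaptive_eps", "dbscan_cluster",
    "clusters_from_labels", "merge_clusters", "volume_filter", "count_buds",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Knobs of the bud clustering and counting pipeline.

    Defaults suit the synthetic generator's default scene (slender buds of
    overall half-length ~0.05 scene units); ``avg_bud_radius`` is the spatial
    radius of a whole bud and must reflect the actual bud scale of the data.
    min_pts, the eps factor and the kNN sizes are engineering defaults, not
    values with an external source.
    """

    min_pts: int = 8
    eps: float | str = "adaptive"     # positive float, or "adaptive"
    knn_for_eps: int = 8
    knn_for_normals: int = 12
    clamp_angle_deg: float = 15.0
    avg_bud_radius: float = 0.05
    min_volume_fraction: float = 0.1
    eps_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.min_pts < 1:
            raise ConfigurationError(f"min_pts must be >= 1, got {self.min_pts}")
        if isinstance(self.eps, str):
            if self.eps != "adaptive":
                raise ConfigurationError(f"eps must be positive or 'adaptive', got {self.eps!r}")
        elif self.eps <= 0:
            raise ConfigurationError(f"eps must be positive, got {self.eps}")
        if not 0 < self.clamp_angle_deg <= 180:
            raise ConfigurationError("clamp_angle_deg must lie in (0, 180]")
        if self.avg_bud_radius <= 0:
            raise ConfigurationError("avg_bud_radius must be positive")
        if not 0 < self.min_volume_fraction < 1:
            raise ConfigurationError("min_volume_fraction must lie in (0, 1)")


@dataclass
class BudCluster:
    """One candidate tea-bud instance: an indexed subset of a cloud."""

    point_indices: np.ndarray
    centroid: np.ndarray
    volume: float
    mean_normal: np.ndarray

    @classmethod
    def from_points(cls, indices: np.ndarray, positions: np.ndarray,
                    normals: np.ndarray | None = None) -> "BudCluster":
        indices = np.asarray(indices, dtype=np.int64)
        if len(indices) == 0:
            raise ValueError("a BudCluster needs at least one point")
        pts = positions[indices]
        if normals is not None:
            mn = normals[indices].mean(axis=0)
            nrm = np.linalg.norm(mn)
            mean_normal = mn / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        else:
            mean_normal = np.array([0.0, 0.0, 1.0])
        return cls(point_indices=indices, centroid=pts.mean(axis=0),
                   volume=hull_volume(pts), mean_normal=mean_normal)


def hull_volume(points: np.ndarray) -> float:
    """3D convex-hull volume; degenerate hulls (flat/collinear/small) are 0."""
    if len(points) < 4:
        return 0.0
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return 0.0


def estimate_normals(cloud: SemanticPointCloud, k: int) -> np.ndarray:
    """Per-point unit normals from local PCA over k nearest neighbors.

    The normal is the eigenvector of the neighborhood covariance with the
    smallest eigenvalue. Signs are fixed so the z component is non-negative;
    on ties (z == 0) the x, then y component is made positive.
    """
    n = len(cloud)
    if k < 3:
        raise InsufficientPointsError(f"k must be >= 3, got {k}")
    if n <= k:
        raise InsufficientPointsError(f"need more than k={k} points, got {n}")
    pos = cloud.positions
    tree = cKDTree(pos)
    _, idx = tree.query(pos, k=k + 1)  # includes self
    nbrs = pos[idx]                    # (n, k+1, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / (k + 1)
    _, vecs = np.linalg.eigh(cov)      # ascending eigenvalues
    normals = vecs[:, :, 0]
    # deterministic sign fix: z >= 0, tie-break on +x then +y
    flip = (normals[:, 2] < 0)
    zz = normals[:, 2] == 0
    flip |= zz & (normals[:, 0] < 0)
    flip |= zz & (normals[:, 0] == 0) & (normals[:, 1] < 0)
    normals[flip] *= -1.0
    return normals


def adaptive_eps(cloud: SemanticPointCloud, k: int, factor: float = 1.5) -> float:
    """Density-adaptive DBSCAN radius: median k-th-NN distance times factor."""
    n = len(cloud)
    if n <= k:
        raise InsufficientPointsError(f"need more than k={k} points, got {n}")
    tree = cKDTree(cloud.positions)
    dists, _ = tree.query(cloud.positions, k=k + 1)
    return float(np.median(dists[:, k]) * factor)


def dbscan_cluster(cloud: SemanticPointCloud, cfg: ClusteringConfig,
                   normals: np.ndarray | None = None) -> np.ndarray:
    """DBSCAN labels (-1 = noise) with the normal-consistency constraint.

    Two points are neighbors iff their distance is <= eps and the angle
    between their normals, taken orientation-insensitively as
    min(theta, 180 - theta), is <= the clamp angle. Core points have at
    least min_pts such neighbors (self included). Cluster expansion follows
    the classic index-ordered algorithm, so clamp_angle_deg = 180 reproduces
    a standard DBSCAN labelling exactly.
    """
    n = len(cloud)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if isinstance(cfg.eps, str):
        if cfg.eps != "adaptive":
            raise ConfigurationError(f"unresolved eps {cfg.eps!r}")
        eps = adaptive_eps(cloud, cfg.knn_for_eps, cfg.eps_factor)
    else:
        eps = float(cfg.eps)
    constrained = cfg.clamp_angle_deg < 180.0
    if constrained and normals is None:
        raise ConfigurationError(
            "normals are required when clamp_angle_deg < 180")
    cos_min = np.cos(np.deg2rad(cfg.clamp_angle_deg))

    tree = cKDTree(cloud.positions)
    raw = tree.query_ball_point(cloud.positions, eps)
    neighborhoods: list[np.ndarray] = []
    for i, nb in enumerate(raw):
        nb = np.asarray(nb, dtype=np.int64)
        if constrained:
            ok = np.abs(normals[nb] @ normals[i]) >= cos_min - 1e-12
            nb = nb[ok]
        neighborhoods.append(np.sort(nb))
    n_neighbors = np.array([len(nb) for nb in neighborhoods])
    is_core = n_neighbors >= cfg.min_pts

    # classic expansion, same order as sklearn's dbscan_inner
    labels = np.full(n, -1, dtype=np.int64)
    label_num = 0
    stack: list[int] = []
    for i in range(n):
        if labels[i] != -1 or not is_core[i]:
            continue
        while True:
            if labels[i] == -1:
                labels[i] = label_num
                if is_core[i]:
                    for v in neighborhoods[i]:
                        if labels[v] == -1:
                            stack.append(int(v))
            if not stack:
                break
            i = stack.pop()
        label_num += 1
    return labels


def clusters_from_labels(cloud: SemanticPointCloud, labels: np.ndarray,
                         normals: np.ndarray | None = None) -> list[BudCluster]:
    """Build BudCluster objects from DBSCAN labels, ignoring noise (-1)."""
    out = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        idx = np.flatnonzero(labels == lab)
        out.append(BudCluster.from_points(idx, cloud.positions, normals))
    return out


def merge_clusters(clusters: list[BudCluster], avg_bud_radius: float,
                   positions: np.ndarray | None = None,
                   normals: np.ndarray | None = None) -> list[BudCluster]:
    """Merge clusters whose centroids are closer than the average bud radius.

    The merge is transitive: clusters are nodes of a graph with edges where
    the centroid distance is strictly below ``avg_bud_radius``, and each
    connected component becomes one cluster. Centroids and volumes are
    recomputed from the union when positions are given; otherwise centroids
    are size-weighted means and volumes are summed (approximation).
    """
    if avg_bud_radius <= 0:
        raise ConfigurationError("avg_bud_radius must be positive")
    m = len(clusters)
    if m <= 1:
        return list(clusters)
    cents = np.vstack([c.centroid for c in clusters])
    diff = cents[:, None, :] - cents[None, :, :]
    close = np.linalg.norm(diff, axis=2) < avg_bud_radius  # strict <
    np.fill_diagonal(close, False)
    n_comp, comp = connected_components(csr_matrix(close), directed=False)
    merged: list[BudCluster] = []
    for c in range(n_comp):
        members = [clusters[j] for j in np.flatnonzero(comp == c)]
        if len(members) == 1:
            merged.append(members[0])
            continue
        idx = np.concatenate([mm.point_indices for mm in members])
        idx = np.sort(idx)
        if positions is not None:
            merged.append(BudCluster.from_points(idx, positions, normals))
        else:
            sizes = np.array([len(mm.point_indices) for mm in members], dtype=float)
            centroid = np.average(np.vstack([mm.centroid for mm in members]),
                                  axis=0, weights=sizes)
            mn = np.sum([mm.mean_normal * s for mm, s in zip(members, sizes)], axis=0)
            nrm = np.linalg.norm(mn)
            merged.append(BudCluster(
                point_indices=idx, centroid=centroid,
                volume=float(sum(mm.volume for mm in members)),
                mean_normal=mn / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])))
    merged.sort(key=lambda c: int(c.point_indices[0]))
    return merged


def volume_filter(clusters: list[BudCluster],
                  min_volume_fraction: float) -> list[BudCluster]:
    """Drop clusters whose hull volume is below a fraction of the median."""
    if not clusters:
        return []
    vols = np.array([c.volume for c in clusters])
    cutoff = min_volume_fraction * float(np.median(vols))
    return [c for c, v in zip(clusters, vols) if v >= cutoff]


def count_buds(cloud: SemanticPointCloud,
               cfg: ClusteringConfig) -> tuple[int, list[BudCluster]]:
    """Full counting pipeline on a bud cloud; returns (count, clusters)."""
    n = len(cloud)
    if n == 0:
        return 0, []
    min_needed = max(cfg.knn_for_normals, cfg.knn_for_eps) + 1
    if n < min_needed:
        # too few points to even form one bud-sized cluster
        return 0, []
    normals = (estimate_normals(cloud, cfg.knn_for_normals)
               if cfg.clamp_angle_deg < 180.0 else None)
    labels = dbscan_cluster(cloud, cfg, normals)
    clusters = clusters_from_labels(cloud, labels, normals)
    clusters = merge_clusters(clusters, cfg.avg_bud_radius,
                              positions=cloud.positions, normals=normals)
    clusters = volume_filter(clusters, cfg.min_volume_fraction)
    return len(clusters), clusters
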