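"""Harvesting-oriented candidate picking-point estimation per bud cluster.

For each bud cluster the lowest height-range fraction of points (default the
lowest 5% of the z extent) approximates the basal, attachment-side surface of
the bud. A seeded RANSAC plane is fitted to that subset and the candidate
point is either the geometric center of the fitted plane (inlier centroid
projected onto the plane, the default) or the basal-extreme inlier along the
fitted-plane normal. When the fit is degenerate the centroid of the basal
subset is used instead. Candidates can
be displaced along the negative plane normal by a scaled distance dk to
probe stability/displacement trade-offs, and three baselines are provided
for comparison: the basal-subset centroid, the full-cluster centroid, and
the extreme point along the principal axis on the lower side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyClusterError, MissingNormalError

__all__ = [
    "PickingConfig", "PlaneFit", "CandidatePoint",
    "basal_subset", "ransac_plane", "candidate_point",
    "offset_candidate", "baseline_candidates",
    "METHOD_NAMES", "OFFSET_DKS",
]

METHOD_NAMES = ("ours", "low_centroid", "cluster_centroid", "pca_low", "ours_offset")
OFFSET_DKS = (1.5, 3.0, 5.0)  # the evaluated offset settings
_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class PickingConfig:
    """Parameters of basal-subset selection and RANSAC plane fitting."""

    basal_fraction: float = 0.05
    ransac_dist: float = 0.005
    ransac_iters: int = 100
    min_inlier_ratio: float = 0.2
    strategy: str = "plane_center"          # or "min_projection"
    seed: int = 0
    basal_mode: str = "z_range"             # or "count_quantile"

    def __post_init__(self) -> None:
        if not 0 < self.basal_fraction <= 1:
            raise ValueError("basal_fraction must lie in (0, 1]")
        if self.ransac_dist <= 0 or self.ransac_iters < 1:
            raise ValueError("ransac_dist must be positive and ransac_iters >= 1")
        if not 0 < self.min_inlier_ratio < 1:
            raise ValueError("min_inlier_ratio must lie in (0, 1)")
        if self.strategy not in ("plane_center", "min_projection"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.basal_mode not in ("z_range", "count_quantile"):
            raise ValueError(f"unknown basal_mode {self.basal_mode!r}")


@dataclass
class PlaneFit:
    """A RANSAC plane n.x = d with inliers; degenerate when no plane exists."""

    normal: np.ndarray
    offset_d: float
    inlier_indices: np.ndarray
    degenerate: bool


@dataclass
class CandidatePoint:
    """A 3D picking-guidance point with its producing method."""

    position: np.ndarray
    method: str
    dk: float = 0.0
    cluster_id: int = -1
    plane_normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.method!r}")
        if self.dk > 0 and self.method != "ours_offset":
            raise ValueError("dk > 0 is only valid for ours_offset")


def _orient_down(v: np.ndarray) -> np.ndarray:
    """Unit vector re-oriented to have non-positive z (ties: -x, then -y)."""
    v = v / np.linalg.norm(v)
    if v[2] > 0 or (v[2] == 0 and (v[0] > 0 or (v[0] == 0 and v[1] > 0))):
        return -v
    return v


def basal_subset(points: np.ndarray, fraction: float,
                 mode: str = "z_range") -> np.ndarray:
    """Indices of the lowest height-range fraction of a cluster.

    ``z_range`` keeps points with z <= z_min + fraction * (z_max - z_min)
    (the minimum-z point always qualifies, ties included); ``count_quantile``
    keeps the lowest ceil(fraction * n) points by z instead.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise EmptyClusterError("empty cluster")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    z = points[:, 2]
    if mode == "z_range":
        cut = z.min() + fraction * (z.max() - z.min())
        return np.flatnonzero(z <= cut)
    k = max(1, int(np.ceil(fraction * len(points))))
    order = np.argsort(z, kind="stable")
    return np.sort(order[:k])


def ransac_plane(points: np.ndarray, cfg: PickingConfig) -> PlaneFit:
    """Seeded RANSAC plane fit with least-squares refinement on the inliers.

    Samples 3 non-collinear points per iteration, scores by the number of
    points within ``ransac_dist`` of the plane, keeps the best consensus and
    refits via SVD. Degenerate when fewer than 3 points are given, all
    samples are collinear, or the best inlier ratio falls below
    ``min_inlier_ratio``.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 1:
        raise EmptyClusterError("empty cluster")
    if n < 3:
        return PlaneFit(normal=np.array([0.0, 0.0, -1.0]), offset_d=0.0,
                        inlier_indices=np.arange(n), degenerate=True)
    rng = np.random.default_rng(cfg.seed)
    best_count = -1
    best_inliers: np.ndarray | None = None
    scale = float(np.linalg.norm(np.ptp(points, axis=0))) or 1.0
    for _ in range(cfg.ransac_iters):
        i, j, k = rng.choice(n, size=3, replace=False)
        v1, v2 = points[j] - points[i], points[k] - points[i]
        nrm = np.cross(v1, v2)
        nn = np.linalg.norm(nrm)
        if nn <= _COLLINEAR_TOL * scale * scale:
            continue
        nrm = nrm / nn
        d = float(nrm @ points[i])
        dist = np.abs(points @ nrm - d)
        inliers = np.flatnonzero(dist <= cfg.ransac_dist)
        if len(inliers) > best_count:
            best_count = len(inliers)
            best_inliers = inliers
    if best_inliers is None or best_count < 3 or best_count < cfg.min_inlier_ratio * n:
        return PlaneFit(normal=np.array([0.0, 0.0, -1.0]), offset_d=0.0,
                        inlier_indices=np.arange(n), degenerate=True)
    # least-squares refit on the consensus set
    pts = points[best_inliers]
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    normal = _orient_down(vt[-1])
    d = float(normal @ center)
    dist = np.abs(points @ normal - d)
    inliers = np.flatnonzero(dist <= cfg.ransac_dist)
    return PlaneFit(normal=normal, offset_d=d, inlier_indices=inliers,
                    degenerate=False)


def candidate_point(points: np.ndarray, cfg: PickingConfig,
                    cluster_id: int = -1) -> CandidatePoint:
    """The "ours" candidate: basal subset -> RANSAC plane -> strategy.

    ``plane_center``: centroid of the plane inliers projected onto the plane.
    ``min_projection``: the basal-extreme inlier along the plane normal —
    the point with the smallest projection onto the upward-oriented normal,
    equivalently the largest onto the downward one (ties broken by smallest
    index). Degenerate fits fall back to the basal-subset centroid.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise EmptyClusterError("empty cluster")
    basal_idx = basal_subset(points, cfg.basal_fraction, cfg.basal_mode)
    basal = points[basal_idx]
    fit = ransac_plane(basal, cfg)
    if fit.degenerate:
        return CandidatePoint(position=basal.mean(axis=0), method="ours",
                              cluster_id=cluster_id, plane_normal=None)
    inl = basal[fit.inlier_indices]
    if cfg.strategy == "plane_center":
        c = inl.mean(axis=0)
        pos = c - (fit.normal @ c - fit.offset_d) * fit.normal
    else:
        proj = inl @ fit.normal  # normal is downward; max = basal extreme
        pos = inl[int(np.argmax(proj))]  # argmax takes the first maximum
    return CandidatePoint(position=np.asarray(pos, dtype=float), method="ours",
                          cluster_id=cluster_id, plane_normal=fit.normal.copy())


def offset_candidate(cp: CandidatePoint, dk: float,
                     base_unit: float) -> CandidatePoint:
    """Displace a candidate along the negative (downward) plane normal.

    The displacement is dk * base_unit along the downward-oriented normal;
    the base unit scales the dimensionless dk to scene units.
    """
    if cp.plane_normal is None:
        raise MissingNormalError("candidate has no fitted-plane normal")
    if dk < 0 or base_unit <= 0:
        raise ValueError("dk must be >= 0 and base_unit positive")
    down = _orient_down(np.asarray(cp.plane_normal, dtype=float))
    return CandidatePoint(position=cp.position + dk * base_unit * down,
                          method="ours_offset", dk=dk, cluster_id=cp.cluster_id,
                          plane_normal=cp.plane_normal.copy())


def baseline_candidates(points: np.ndarray, cfg: PickingConfig,
                        cluster_id: int = -1) -> list[CandidatePoint]:
    """The three reference methods: low_centroid, cluster_centroid, pca_low.

    ``low_centroid`` is the centroid of the basal subset; ``cluster_centroid``
    the centroid of the whole cluster; ``pca_low`` the extreme point along the
    first principal axis, with the axis oriented so its z component is
    non-positive (the lower-side endpoint).
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise EmptyClusterError("empty cluster")
    basal = points[basal_subset(points, cfg.basal_fraction, cfg.basal_mode)]
    centroid = points.mean(axis=0)
    centered = points - centroid
    if len(points) >= 2:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = _orient_down(vt[0])
    else:
        axis = np.array([0.0, 0.0, -1.0])
    proj = centered @ axis
    pca_low = points[int(np.argmax(proj))]
    return [
        CandidatePoint(position=basal.mean(axis=0), method="low_centroid",
                       cluster_id=cluster_id),
        CandidatePoint(position=centroid, method="cluster_centroid",
                       cluster_id=cluster_id),
        CandidatePoint(position=pca_low.copy(), method="pca_low",
                       cluster_id=cluster_id),
    ]
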