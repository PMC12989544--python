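"""Proxy-based localization-stability evaluation of picking-point methods.

Junction-level ground truth for real tea plants is unavailable at scale, so
candidate picking points are judged by repeatability instead: each cluster's
candidate is re-estimated p times under random subsampling (and optional
added noise) and the spread of the repeated estimates is summarized by

* ``mu_p``  — mean pairwise Euclidean distance between the p estimates,
* ``p90_p`` — 90th percentile (linear interpolation) of those pairwise
  distances,
* ``pass rate`` — fraction of estimates whose distance to the mean estimate
  is strictly below a tolerance.

The reference protocol is p = 5 repetitions at subsample ratio 0.5 with no
added noise. Metrics are computed per cluster and averaged (unweighted) over
the clusters of a scene, one report row per (scene, method, dk).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .clustering import BudCluster
from .cloud import SemanticPointCloud
from .errors import InsufficientPointsError, InvalidThresholdError
from .picking import (
    CandidatePoint, PickingConfig, baseline_candidates, candidate_point,
    offset_candidate,
)

__all__ = [
    "StabilityProtocol", "repeated_estimates",
    "mu_p", "p90_p", "pass_rate", "evaluate_methods", "TABLE_METHODS",
]

# (method, dk) rows of the reference comparison
TABLE_METHODS: tuple[tuple[str, float], ...] = (
    ("ours", 0.0),
    ("low_centroid", 0.0),
    ("ours_offset", 1.5),
    ("ours_offset", 3.0),
    ("ours_offset", 5.0),
    ("cluster_centroid", 0.0),
    ("pca_low", 0.0),
)


@dataclass(frozen=True)
class StabilityProtocol:
    """Perturbation protocol of the stability evaluation."""

    p: int = 5
    subsample_ratio: float = 0.5
    noise_sd: float = 0.0
    tolerance: float = 0.01     # pass-rate threshold, scene units (no external source)
    seed: int = 0
    deviation_ref: str = "mean"  # or "median" (geometric median)

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not 0 < self.subsample_ratio <= 1:
            raise ValueError("subsample_ratio must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tolerance <= 0:
            raise InvalidThresholdError("tolerance must be positive")
        if self.deviation_ref not in ("mean", "median"):
            raise ValueError(f"unknown deviation_ref {self.deviation_ref!r}")


def _estimate(points: np.ndarray, method: str, dk: float,
              cfg: PickingConfig, cluster_id: int) -> CandidatePoint:
    """Run one picking method on one point set."""
    if method == "ours":
        return candidate_point(points, cfg, cluster_id)
    if method == "ours_offset":
        cp = candidate_point(points, cfg, cluster_id)
        if cp.plane_normal is None:
            # degenerate fit: no normal to offset along; keep the fallback point
            return replace(cp, method="ours_offset", dk=dk)
        return offset_candidate(cp, dk, base_unit=cfg.ransac_dist)
    for cand in baseline_candidates(points, cfg, cluster_id):
        if cand.method == method:
            return cand
    raise ValueError(f"unknown method {method!r}")


def repeated_estimates(points: np.ndarray, method: str,
                       protocol: StabilityProtocol,
                       cfg: PickingConfig | None = None,
                       dk: float = 0.0,
                       cluster_id: int = -1) -> list[CandidatePoint]:
    """Re-estimate a candidate p times under random subsampling.

    Each repetition draws ceil(ratio * n) points without replacement using a
    derived seed (protocol.seed + repetition index), adds isotropic Gaussian
    noise when noise_sd > 0, and runs the method.
    """
    points = np.asarray(points, dtype=float)
    cfg = cfg or PickingConfig()
    n = len(points)
    m = int(np.ceil(protocol.subsample_ratio * n))
    if m < 3:
        raise InsufficientPointsError(
            f"subsample of {m} points is below the minimum of 3")
    out = []
    for rep in range(protocol.p):
        rng = np.random.default_rng(protocol.seed + rep)
        idx = rng.choice(n, size=m, replace=False)
        sub = points[np.sort(idx)]
        if protocol.noise_sd > 0:
            sub = sub + rng.normal(0.0, protocol.noise_sd, sub.shape)
        out.append(_estimate(sub, method, dk, cfg, cluster_id))
    return out


def _pairwise(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float).reshape(len(points), -1)
    if len(pts) < 2:
        raise InsufficientPointsError("need >= 2 estimates")
    return np.array([np.linalg.norm(a - b) for a, b in combinations(pts, 2)])


def mu_p(points) -> float:
    """Mean pairwise Euclidean distance between repeated estimates."""
    return float(np.mean(_pairwise(points)))


def p90_p(points) -> float:
    """90th percentile (linear interpolation) of the pairwise distances."""
    return float(np.percentile(_pairwise(points), 90))


def pass_rate(points, tolerance: float, reference: str = "mean") -> float:
    """Fraction of estimates strictly within tolerance of the reference point.

    The reference is the arithmetic mean of the estimates, or the geometric
    median (Weiszfeld iteration) when ``reference='median'``.
    """
    if tolerance <= 0:
        raise InvalidThresholdError("tolerance must be positive")
    pts = np.asarray(points, dtype=float).reshape(len(points), -1)
    if len(pts) < 2:
        raise InsufficientPointsError("need >= 2 estimates")
    ref = _geometric_median(pts) if reference == "median" else pts.mean(axis=0)
    dev = np.linalg.norm(pts - ref, axis=1)
    return float(np.mean(dev < tolerance))


def _geometric_median(pts: np.ndarray, iters: int = 200, tol: float = 1e-12) -> np.ndarray:
    x = pts.mean(axis=0)
    for _ in range(iters):
        d = np.linalg.norm(pts - x, axis=1)
        if np.any(d < tol):
            return x
        w = 1.0 / d
        x_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    return x


def evaluate_methods(clusters: list[BudCluster],
                     cloud: SemanticPointCloud,
                     protocol: StabilityProtocol,
                     cfg: PickingConfig | None = None,
                     methods: tuple[tuple[str, float], ...] = TABLE_METHODS,
                     tree_id: str = "scene") -> pd.DataFrame:
    """Stability report over a scene's clusters, one row per (method, dk).

    Per cluster and method the protocol's repeated estimates give mu_p,
    p90_p and pass rate; rows carry the unweighted mean over clusters.
    Clusters too small for the protocol's subsample are skipped.
    """
    cfg = cfg or PickingConfig()
    rows = []
    for method, dk in methods:
        per_cluster = []
        for ci, cluster in enumerate(clusters):
            pts = cloud.positions[cluster.point_indices]
            if int(np.ceil(protocol.subsample_ratio * len(pts))) < 3:
                continue
            ests = repeated_estimates(pts, method, protocol, cfg, dk, ci)
            positions = np.vstack([e.position for e in ests])
            per_cluster.append((
                mu_p(positions), p90_p(positions),
                pass_rate(positions, protocol.tolerance, protocol.deviation_ref),
            ))
        if per_cluster:
            arr = np.asarray(per_cluster)
            mu, p90, pr = arr.mean(axis=0)
        else:
            mu = p90 = pr = float("nan")
        rows.append({"tree_id": tree_id, "method": method, "dk": dk,
                     "mu_p": mu, "p90_p": p90, "pass_rate": pr})
    return pd.DataFrame(rows)
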