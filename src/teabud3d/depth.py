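"""Region-aware reliability analysis of monocular depth predictions.

Monocular depth is scale-ambiguous, so predicted depths are first aligned to
sparse reference depths (e.g. triangulated feature points projected into the
image) by robust median scaling — the median of per-sample ref/pred ratios.
Error statistics are then computed globally and for labeled regions
(thin-branch ROI, dense-foliage ROI, non-ROI control), reusing the global
scale for every region so that region-specific bias stays visible:

* AbsRel — mean of |pred - ref| / ref,
* RMSE — root mean squared error,
* p90 AbsRel — 90th percentile (linear interpolation) of per-sample
  relative errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientPointsError, InvalidDepthError

__all__ = [
    "CameraModel", "DepthSampleSet", "DepthErrorStats",
    "project_points", "median_scale_align", "depth_error_stats",
    "region_report", "REGIONS",
]

REGIONS = ("roi_branch", "roi_foliage", "non_roi")


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: intrinsics (fx, fy, cx, cy) and a world-to-camera pose."""

    fx: float
    fy: float
    cx: float
    cy: float
    rotation: np.ndarray      # (3, 3), world -> camera
    translation: np.ndarray   # (3,)

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
                or not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))


@dataclass
class DepthSampleSet:
    """Sparse reference/predicted depth samples with region labels."""

    pixels: np.ndarray        # (m, 2)
    ref_depth: np.ndarray     # (m,) > 0
    pred_depth: np.ndarray    # (m,) > 0
    region: np.ndarray        # (m,) labels from REGIONS

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float).reshape(-1, 2)
        self.ref_depth = np.asarray(self.ref_depth, dtype=float).reshape(-1)
        self.pred_depth = np.asarray(self.pred_depth, dtype=float).reshape(-1)
        self.region = np.asarray(self.region).reshape(-1)
        m = len(self.pixels)
        for name in ("ref_depth", "pred_depth", "region"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected {m}")
        if m and (self.ref_depth.min() <= 0 or self.pred_depth.min() <= 0):
            raise InvalidDepthError("depths must be positive")
        unknown = set(np.unique(self.region)) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class DepthErrorStats:
    n_points: int
    abs_rel: float
    rmse: float
    p90_abs_rel: float


def project_points(points3d: np.ndarray, cam: CameraModel,
                   image_size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pinhole projection of world points; returns (pixels, depths, visible).

    ``image_size`` is (width, height). A point is visible iff its camera-space
    depth Z is positive and its pixel lies inside [0, W) x [0, H).
    """
    pts = np.asarray(points3d, dtype=float).reshape(-1, 3)
    cam_pts = pts @ cam.rotation.T + cam.translation
    z = cam_pts[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = cam.fx * cam_pts[:, 0] / z + cam.cx
        v = cam.fy * cam_pts[:, 1] / z + cam.cy
    w, h = image_size
    visible = (z > 0) & (u >= 0) & (u < w) & (v >= 0) & (v < h)
    return np.column_stack([u, v]), z, visible


def median_scale_align(pred: np.ndarray, ref: np.ndarray) -> tuple[float, np.ndarray]:
    """Robust median scaling: s = median(ref / pred); returns (s, s * pred).

    A ``ratio_of_medians`` alternative (median(ref) / median(pred)) exists as
    :func:`ratio_of_medians_scale` for comparison.
    """
    pred = np.asarray(pred, dtype=float).reshape(-1)
    ref = np.asarray(ref, dtype=float).reshape(-1)
    if len(pred) == 0:
        raise InsufficientPointsError("need at least one sample")
    if pred.min() <= 0 or ref.min() <= 0:
        raise InvalidDepthError("depths must be positive")
    s = float(np.median(ref / pred))
    return s, s * pred


def ratio_of_medians_scale(pred: np.ndarray, ref: np.ndarray) -> tuple[float, np.ndarray]:
    """Alternative alignment: s = median(ref) / median(pred)."""
    pred = np.asarray(pred, dtype=float).reshape(-1)
    ref = np.asarray(ref, dtype=float).reshape(-1)
    if len(pred) == 0:
        raise InsufficientPointsError("need at least one sample")
    if pred.min() <= 0 or ref.min() <= 0:
        raise InvalidDepthError("depths must be positive")
    s = float(np.median(ref) / np.median(pred))
    return s, s * pred


def depth_error_stats(aligned_pred: np.ndarray, ref: np.ndarray,
                      mask: np.ndarray | None = None) -> DepthErrorStats:
    """AbsRel, RMSE and p90 AbsRel of aligned predictions vs references."""
    aligned_pred = np.asarray(aligned_pred, dtype=float).reshape(-1)
    ref = np.asarray(ref, dtype=float).reshape(-1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).reshape(-1)
        aligned_pred, ref = aligned_pred[mask], ref[mask]
    if len(ref) == 0:
        raise InsufficientPointsError("empty subset")
    err = aligned_pred - ref
    rel = np.abs(err) / ref
    return DepthErrorStats(
        n_points=len(ref),
        abs_rel=float(np.mean(rel)),
        rmse=float(np.sqrt(np.mean(err ** 2))),
        p90_abs_rel=float(np.percentile(rel, 90)),
    )


def region_report(samples: DepthSampleSet,
                  scale_mode: str = "median_of_ratios") -> pd.DataFrame:
    """Per-region error table: Global plus each labeled region.

    The alignment scale is estimated once on all samples (Global) and reused
    for every region, so that a region-specific depth bias shows up in the
    region's statistics rather than being absorbed by a local rescale. Empty
    regions get a row with n_points = 0 and missing (NaN) statistics.
    """
    align = {"median_of_ratios": median_scale_align,
             "ratio_of_medians": ratio_of_medians_scale}[scale_mode]
    scale, aligned = align(samples.pred_depth, samples.ref_depth)
    rows = []
    g = depth_error_stats(aligned, samples.ref_depth)
    rows.append({"region": "Global", "n_points": g.n_points, "abs_rel": g.abs_rel,
                 "rmse": g.rmse, "p90_abs_rel": g.p90_abs_rel, "scale": scale})
    for region in REGIONS:
        mask = samples.region == region
        if mask.any():
            st = depth_error_stats(aligned, samples.ref_depth, mask)
            rows.append({"region": region, "n_points": st.n_points,
                         "abs_rel": st.abs_rel, "rmse": st.rmse,
                         "p90_abs_rel": st.p90_abs_rel, "scale": scale})
        else:
            rows.append({"region": region, "n_points": 0, "abs_rel": np.nan,
                         "rmse": np.nan, "p90_abs_rel": np.nan, "scale": scale})
    return pd.DataFrame(rows)
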