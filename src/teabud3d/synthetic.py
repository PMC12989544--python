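"""Seeded synthetic tea-tree scene generator with full ground truth.

Emulates the point clouds obtained by sampling a semantic radiance field of a
tea tree: a surface-concentrated foliage shell, prolate-ellipsoid tea-bud
clusters attached to the canopy, and low-density "floater" points with
spuriously high bud probability strung along camera viewing rays (the
artifact that density gating removes). Every scene carries a
:class:`SceneTruth` with the exact bud count, per-bud memberships, basal
attachment points and basal-plane normals, so that clustering, counting and
picking-point estimation can be tested as parameter recovery.

All geometry is in dimensionless scene units; no metric scale is claimed
(monocular reconstruction is scale-ambiguous). The z axis is vertical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .boxes import BoundingBox
from .cloud import SemanticPointCloud
from .errors import InvalidSpecError

__all__ = ["SceneSpec", "SceneTruth", "generate_tree", "generate_box_pairs"]

# Density/probability bands of the stated world. Bud-surface points always
# pass the sigma >= 0.45 density gate and carry bud probability >= 0.9;
# floaters always sit strictly below the gate.
_BUD_SIGMA = (0.60, 1.00)
_BUD_PROB = (0.90, 1.00)
_FOLIAGE_SIGMA = (0.50, 1.00)
_FOLIAGE_PROB = (0.00, 0.20)
_FLOATER_SIGMA = (0.05, 0.40)
_FLOATER_PROB = (0.90, 1.00)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic tea-tree scene.

    Defaults describe a ~1-unit-radius canopy carrying 30 slender buds:
    mean equatorial radius 0.01 units, elongated 5x along the axis (a young
    "single bud" tea shoot is several times taller than wide), tilted up to
    30 degrees from vertical so laterally growing buds occur, with 2400
    surface samples on a mean-size bud (actual counts scale with surface
    area, keeping point spacing uniform), a dense foliage shell, 5%
    floaters, 10% occlusion dropout and positional noise of 0.001 units.
    """

    n_buds: int = 30
    canopy_radius: float = 1.0
    bud_radius_mean: float = 0.01
    bud_radius_sd: float = 0.0015
    bud_elongation: float = 5.0
    bud_tilt_max_deg: float = 30.0
    points_per_bud: int = 2400
    foliage_points: int = 8000
    floater_fraction: float = 0.05
    occlusion_dropout: float = 0.10
    noise_sd: float = 0.001
    seed: int = 0
    # Minimum spacing between bud attachment points; None -> 1.2 x the mean
    # bud length (tilted slender buds stay separable by construction).
    min_separation: float | None = None

    def __post_init__(self) -> None:
        if self.n_buds <= 0:
            raise InvalidSpecError(f"n_buds must be positive, got {self.n_buds}")
        if self.points_per_bud <= 0:
            raise InvalidSpecError(f"points_per_bud must be positive, got {self.points_per_bud}")
        if self.canopy_radius <= 0 or self.bud_radius_mean <= 0 or self.bud_radius_sd < 0:
            raise InvalidSpecError("canopy_radius and bud radii must be positive")
        if self.bud_elongation < 1:
            raise InvalidSpecError(f"bud_elongation must be >= 1, got {self.bud_elongation}")
        if not 0 <= self.bud_tilt_max_deg <= 90:
            raise InvalidSpecError("bud_tilt_max_deg must lie in [0, 90]")
        if self.foliage_points < 0:
            raise InvalidSpecError("foliage_points must be non-negative")
        if not 0 <= self.floater_fraction <= 1:
            raise InvalidSpecError("floater_fraction must lie in [0, 1]")
        if not 0 <= self.occlusion_dropout < 1:
            raise InvalidSpecError("occlusion_dropout must lie in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")

    @property
    def separation(self) -> float:
        if self.min_separation is not None:
            return self.min_separation
        return 1.2 * (2.0 * self.bud_radius_mean * self.bud_elongation)


@dataclass
class SceneTruth:
    """Generator-side ground truth for one synthetic scene."""

    bud_count: int
    bud_memberships: list[np.ndarray]
    basal_points: np.ndarray      # (n_buds, 3)
    basal_normals: np.ndarray     # (n_buds, 3), unit, = bud axis direction
    bud_axes: np.ndarray          # (n_buds, 3), unit, basal end -> apex

    def to_json(self, path) -> None:
        payload = {
            "bud_count": int(self.bud_count),
            "bud_memberships": [m.tolist() for m in self.bud_memberships],
            "basal_points": self.basal_points.tolist(),
            "basal_normals": self.basal_normals.tolist(),
            "bud_axes": self.bud_axes.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SceneTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            bud_count=d["bud_count"],
            bud_memberships=[np.asarray(m, dtype=np.int64) for m in d["bud_memberships"]],
            basal_points=np.asarray(d["basal_points"], dtype=np.float64),
            basal_normals=np.asarray(d["basal_normals"], dtype=np.float64),
            bud_axes=np.asarray(d["bud_axes"], dtype=np.float64),
        )


def _uniform_hemisphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit directions uniform on the upper hemisphere (z >= 0)."""
    z = rng.uniform(0.0, 1.0, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    s = np.sqrt(1.0 - z ** 2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _unit_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying +z onto the given unit axis."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _place_attachments(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    """Bud attachment points on the canopy with minimum pairwise spacing."""
    placed: list[np.ndarray] = []
    sep2 = spec.separation ** 2
    tries = 0
    max_tries = 20000 * spec.n_buds
    while len(placed) < spec.n_buds:
        tries += 1
        if tries > max_tries:
            raise InvalidSpecError(
                f"cannot place {spec.n_buds} buds with separation {spec.separation} "
                f"on a canopy of radius {spec.canopy_radius}")
        cand = spec.canopy_radius * _uniform_hemisphere(rng, 1)[0]
        if all(np.sum((cand - p) ** 2) >= sep2 for p in placed):
            placed.append(cand)
    return np.asarray(placed)


def generate_tree(spec: SceneSpec) -> tuple[SemanticPointCloud, SceneTruth]:
    """Generate one synthetic tea-tree cloud plus its ground truth.

    Point order: foliage shell, then bud 0..n_buds-1 in order, then floaters.
    Each bud is a prolate ellipsoid (equatorial radius r, polar radius
    r x elongation) whose lower axis end is attached to the canopy; the basal
    point is that attachment-end surface point as emitted in the cloud (it is
    always retained through occlusion dropout, since the attachment side is
    where the bud meets the branch), and the basal-plane normal is the bud
    axis. Floaters lie on segments joining ring-of-viewpoint positions to bud
    centers, mimicking semantic leakage along lines of sight.
    """
    rng = np.random.default_rng(spec.seed)
    attachments = _place_attachments(rng, spec)

    positions, colors, density, bud_prob, label = [], [], [], [], []

    # -- foliage shell: surface-concentrated, high density, low bud probability
    nf = spec.foliage_points
    if nf:
        dirs = _uniform_hemisphere(rng, nf)
        radii = spec.canopy_radius * (1.0 + rng.normal(0.0, 0.02, nf))
        positions.append(dirs * radii[:, None])
        colors.append(np.column_stack([rng.uniform(0.05, 0.25, nf),
                                       rng.uniform(0.35, 0.6, nf),
                                       rng.uniform(0.05, 0.2, nf)]))
        density.append(rng.uniform(*_FOLIAGE_SIGMA, nf))
        bud_prob.append(rng.uniform(*_FOLIAGE_PROB, nf))
        label.append(np.full(nf, -1, dtype=np.int32))

    # -- buds
    basal_points = np.zeros((spec.n_buds, 3))
    axes = np.zeros((spec.n_buds, 3))
    bud_sizes: list[int] = []
    bud_centers = np.zeros((spec.n_buds, 3))
    for b in range(spec.n_buds):
        r_eq = max(rng.normal(spec.bud_radius_mean, spec.bud_radius_sd),
                   0.5 * spec.bud_radius_mean)
        r_pol = r_eq * spec.bud_elongation
        tilt = np.deg2rad(rng.uniform(0.0, spec.bud_tilt_max_deg))
        azim = rng.uniform(0.0, 2 * np.pi)
        axis = np.array([np.sin(tilt) * np.cos(azim),
                         np.sin(tilt) * np.sin(azim),
                         np.cos(tilt)])
        rot = _rotation_to(axis)
        center = attachments[b] + axis * r_pol  # basal axis end on the canopy

        # constant spatial sampling density: points scale with surface area,
        # so buds of different sizes share one point spacing (as a radiance
        # field sampled on a uniform grid would produce)
        m = max(16, int(round(spec.points_per_bud * (r_eq / spec.bud_radius_mean) ** 2)))
        sphere = _unit_sphere(rng, m)
        # first sample pinned to the basal pole so the attachment point is in
        # the cloud; it survives occlusion dropout by construction
        sphere[0] = [0.0, 0.0, -1.0]
        local = sphere * np.array([r_eq, r_eq, r_pol])
        pts = local @ rot.T + center

        # per-point channels are drawn for the full sample and subset after,
        # so the generator's random stream is independent of the dropout rate
        keep = rng.random(m) < (1.0 - spec.occlusion_dropout)
        keep[0] = True
        col = np.column_stack([rng.uniform(0.5, 0.75, m),
                               rng.uniform(0.7, 0.9, m),
                               rng.uniform(0.2, 0.4, m)])
        sig = rng.uniform(*_BUD_SIGMA, m)
        prob = rng.uniform(*_BUD_PROB, m)
        mk = int(keep.sum())
        positions.append(pts[keep])
        colors.append(col[keep])
        density.append(sig[keep])
        bud_prob.append(prob[keep])
        label.append(np.full(mk, b, dtype=np.int32))
        bud_sizes.append(mk)
        axes[b] = axis
        bud_centers[b] = center

    # -- floaters along viewing rays
    n_solid = int(nf + sum(bud_sizes))
    n_float = int(round(spec.floater_fraction * n_solid))
    if n_float:
        ring = np.deg2rad(rng.uniform(0.0, 360.0, 8))
        views = np.column_stack([3 * spec.canopy_radius * np.cos(ring),
                                 3 * spec.canopy_radius * np.sin(ring),
                                 np.full(8, spec.canopy_radius)])
        vi = rng.integers(0, len(views), n_float)
        bi = rng.integers(0, spec.n_buds, n_float)
        t = rng.uniform(0.15, 0.85, n_float)[:, None]
        pts = views[vi] + t * (bud_centers[bi] - views[vi])
        pts = pts + rng.normal(0.0, 0.02 * spec.canopy_radius, pts.shape)
        positions.append(pts)
        colors.append(rng.uniform(0.2, 0.8, (n_float, 3)))
        density.append(rng.uniform(*_FLOATER_SIGMA, n_float))
        bud_prob.append(rng.uniform(*_FLOATER_PROB, n_float))
        label.append(np.full(n_float, -1, dtype=np.int32))

    pos = np.vstack(positions)
    if spec.noise_sd > 0:
        pos = pos + rng.normal(0.0, spec.noise_sd, pos.shape)

    cloud = SemanticPointCloud(
        positions=pos,
        colors=np.vstack(colors),
        density=np.concatenate(density),
        bud_prob=np.concatenate(bud_prob),
        label=np.concatenate(label),
    )

    memberships = []
    offset = nf
    for b in range(spec.n_buds):
        memberships.append(np.arange(offset, offset + bud_sizes[b], dtype=np.int64))
        # emitted (noisy) position of the pinned attachment sample
        basal_points[b] = pos[offset]
        offset += bud_sizes[b]

    truth = SceneTruth(
        bud_count=spec.n_buds,
        bud_memberships=memberships,
        basal_points=basal_points,
        basal_normals=axes.copy(),
        bud_axes=axes.copy(),
    )
    return cloud, truth


def generate_box_pairs(n: int, seed: int) -> list[tuple[BoundingBox, BoundingBox]]:
    """Reproducible random box pairs for IoU property tests.

    A fixed 20% of pairs are disjoint, 20% are strictly nested, and the rest
    overlap at random.
    """
    if n <= 0:
        raise InvalidSpecError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[BoundingBox, BoundingBox]] = []
    kinds = np.array(["disjoint", "nested", "random"])[
        np.r_[np.zeros(max(1, n // 5), int), np.ones(max(1, n // 5), int),
              np.full(max(0, n - 2 * max(1, n // 5)), 2, int)][:n]]
    for kind in kinds:
        xc, yc = rng.uniform(-10, 10, 2)
        w, h = rng.uniform(0.5, 5.0, 2)
        a = BoundingBox(xc, yc, w, h)
        if kind == "disjoint":
            w2, h2 = rng.uniform(0.5, 5.0, 2)
            gap = rng.uniform(0.1, 3.0)
            b = BoundingBox(xc + (w + w2) / 2 + gap, yc + rng.uniform(-2, 2), w2, h2)
        elif kind == "nested":
            f = rng.uniform(0.1, 0.5)
            w2, h2 = f * w, f * h
            b = BoundingBox(xc + rng.uniform(-1, 1) * (w - w2) / 2,
                            yc + rng.uniform(-1, 1) * (h - h2) / 2, w2, h2)
        else:
            b = BoundingBox(xc + rng.uniform(-w, w), yc + rng.uniform(-h, h),
                            *rng.uniform(0.5, 5.0, 2))
        pairs.append((a, b))
    return pairs
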