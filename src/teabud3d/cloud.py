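"""Semantic point-cloud container, PLY I/O, and the filtering stages.

The central exchange type is :class:`SemanticPointCloud`: points sampled from a
semantic radiance field, each carrying a position, an optional RGB color, a
volume density ``sigma`` (high on solid surfaces, low in empty space), a
bud-semantic probability, and an optional instance label (-1 = non-bud).

Three filters operate on it:

* :func:`dsc_filter` — density-symmetric coupling: a semantic prediction is
  trusted only where the density field indicates a solid surface
  (``sigma >= 0.45`` by default), which suppresses semantic "floaters" in
  empty space.
* :func:`statistical_outlier_removal` — the classic mean-kNN-distance filter.
* :func:`radius_outlier_removal` — drop points with too few neighbors inside
  a fixed radius.

PLY files use a small dialect with per-vertex properties ``x,y,z`` (float32),
``red,green,blue`` (uint8), ``density`` (float32), ``semantic`` (float32) and
``label`` (int32); unknown vertex properties survive a read/write round trip.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    InsufficientPointsError,
    InvalidThresholdError,
    PlyFormatError,
)

__all__ = [
    "SemanticPointCloud",
    "dsc_filter",
    "dsc_masks",
    "radius_outlier_removal",
    "radius_outlier_mask",
    "statistical_outlier_removal",
    "statistical_outlier_mask",
    "read_ply",
    "write_ply",
]

DSC_SIGMA_MIN = 0.45  # density gate below which semantic labels are discarded


@dataclass
class SemanticPointCloud:
    """Point cloud with per-point density, semantic probability and label.

    Parameters
    ----------
    positions : (n, 3) float array
        Point coordinates in scene units; the z axis is vertical (gravity).
    colors : (n, 3) float array in [0, 1], optional
        RGB per point.
    density : (n,) float array, >= 0
        Volume density sigma of the radiance field at each point.
    bud_prob : (n,) float array in [0, 1]
        Semantic probability that the point belongs to a tea bud.
    label : (n,) int array, optional
        Instance id per point, -1 for non-bud points.
    extras : dict of name -> (n,) array
        Unknown PLY vertex properties, preserved verbatim on write.
    """

    positions: np.ndarray
    colors: np.ndarray | None = None
    density: np.ndarray | None = None
    bud_prob: np.ndarray | None = None
    label: np.ndarray | None = None
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        n = len(self.positions)
        if self.density is None:
            self.density = np.ones(n)
        if self.bud_prob is None:
            self.bud_prob = np.zeros(n)
        if self.label is None:
            self.label = np.full(n, -1, dtype=np.int32)
        self.density = np.asarray(self.density, dtype=np.float64).reshape(-1)
        self.bud_prob = np.asarray(self.bud_prob, dtype=np.float64).reshape(-1)
        self.label = np.asarray(self.label, dtype=np.int32).reshape(-1)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)
        self.validate()

    def validate(self) -> None:
        n = len(self.positions)
        for name in ("density", "bud_prob", "label"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected {n}")
        if self.colors is not None and len(self.colors) != n:
            raise ValueError(f"colors has length {len(self.colors)}, expected {n}")
        for name, arr in self.extras.items():
            if len(arr) != n:
                raise ValueError(f"extra property {name!r} has length {len(arr)}, expected {n}")
        if n and np.min(self.density) < 0:
            raise ValueError("density must be non-negative")
        if n and (np.min(self.bud_prob) < 0 or np.max(self.bud_prob) > 1):
            raise ValueError("bud_prob must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.positions)

    def select(self, index) -> "SemanticPointCloud":
        """Sub-cloud at the given indices or boolean mask, order-preserving."""
        index = np.asarray(index)
        return SemanticPointCloud(
            positions=self.positions[index],
            colors=None if self.colors is None else self.colors[index],
            density=self.density[index],
            bud_prob=self.bud_prob[index],
            label=self.label[index],
            extras={k: v[index] for k, v in self.extras.items()},
        )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def dsc_masks(cloud: SemanticPointCloud, sigma_min: float = DSC_SIGMA_MIN,
              prob_min: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (tree, bud) masks of the density-symmetric coupling filter."""
    if sigma_min < 0:
        raise InvalidThresholdError(f"sigma_min must be >= 0, got {sigma_min}")
    if not 0 <= prob_min <= 1:
        raise InvalidThresholdError(f"prob_min must lie in [0, 1], got {prob_min}")
    tree_mask = cloud.density >= sigma_min
    bud_mask = tree_mask & (cloud.bud_prob >= prob_min)
    return tree_mask, bud_mask


def dsc_filter(cloud: SemanticPointCloud, sigma_min: float = DSC_SIGMA_MIN,
               prob_min: float = 0.5) -> tuple[SemanticPointCloud, SemanticPointCloud]:
    """Split a cloud into (tree, bud) by density gating of semantic labels.

    ``tree`` keeps points whose density passes ``sigma_min`` (solid surface);
    ``bud`` additionally requires a bud probability of at least ``prob_min``.
    Both thresholds are inclusive and input order is preserved.
    """
    tree_mask, bud_mask = dsc_masks(cloud, sigma_min, prob_min)
    return cloud.select(tree_mask), cloud.select(bud_mask)


def radius_outlier_mask(cloud: SemanticPointCloud, radius: float,
                        min_neighbors: int) -> np.ndarray:
    """Mask of points having >= ``min_neighbors`` others within ``radius``."""
    if radius <= 0:
        raise InvalidThresholdError(f"radius must be positive, got {radius}")
    if min_neighbors < 1:
        raise InvalidThresholdError(f"min_neighbors must be >= 1, got {min_neighbors}")
    n = len(cloud)
    if n == 0:
        return np.zeros(0, dtype=bool)
    tree = cKDTree(cloud.positions)
    counts = tree.query_ball_point(cloud.positions, radius, return_length=True)
    return np.asarray(counts) - 1 >= min_neighbors  # self is always counted


def radius_outlier_removal(cloud: SemanticPointCloud, radius: float,
                           min_neighbors: int) -> SemanticPointCloud:
    """Single-pass radius filter: drop points with too few neighbors."""
    return cloud.select(radius_outlier_mask(cloud, radius, min_neighbors))


def statistical_outlier_mask(cloud: SemanticPointCloud, k: int,
                             std_ratio: float) -> np.ndarray:
    """Mask of points whose mean k-NN distance is within mean + ratio * sd."""
    if k < 1:
        raise InvalidThresholdError(f"k must be >= 1, got {k}")
    if std_ratio <= 0:
        raise InvalidThresholdError(f"std_ratio must be positive, got {std_ratio}")
    n = len(cloud)
    if n <= k:
        raise InsufficientPointsError(f"need more than k={k} points, got {n}")
    tree = cKDTree(cloud.positions)
    dists, _ = tree.query(cloud.positions, k=k + 1)
    mean_knn = dists[:, 1:].mean(axis=1)  # drop the zero self-distance
    bound = mean_knn.mean() + std_ratio * mean_knn.std()
    return mean_knn <= bound


def statistical_outlier_removal(cloud: SemanticPointCloud, k: int,
                                std_ratio: float) -> SemanticPointCloud:
    """Single-pass statistical filter on mean distance to k nearest neighbors."""
    return cloud.select(statistical_outlier_mask(cloud, k, std_ratio))


# ---------------------------------------------------------------------------
# PLY I/O
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}
_PLY_NAMES = {v: k for k, v in
              [("char", "i1"), ("uchar", "u1"), ("short", "i2"), ("ushort", "u2"),
               ("int", "i4"), ("uint", "u4"), ("float", "f4"), ("double", "f8")]}

_CANONICAL = ("x", "y", "z", "red", "green", "blue", "density", "semantic", "label")


def write_ply(cloud: SemanticPointCloud, path, binary: bool = True) -> None:
    """Write a cloud to PLY (binary little-endian by default, or ascii).

    Positions/density/semantic are stored as float32, colors as uint8,
    labels as int32; extra properties keep their stored dtype. Output is
    byte-deterministic for identical input arrays.
    """
    n = len(cloud)
    fields: list[tuple[str, str, np.ndarray]] = [
        ("x", "f4", cloud.positions[:, 0].astype(np.float32)),
        ("y", "f4", cloud.positions[:, 1].astype(np.float32)),
        ("z", "f4", cloud.positions[:, 2].astype(np.float32)),
    ]
    if cloud.colors is not None:
        rgb = np.clip(np.rint(cloud.colors * 255.0), 0, 255).astype(np.uint8)
        fields += [("red", "u1", rgb[:, 0]), ("green", "u1", rgb[:, 1]),
                   ("blue", "u1", rgb[:, 2])]
    fields += [
        ("density", "f4", cloud.density.astype(np.float32)),
        ("semantic", "f4", cloud.bud_prob.astype(np.float32)),
        ("label", "i4", cloud.label.astype(np.int32)),
    ]
    for name, arr in cloud.extras.items():
        arr = np.asarray(arr)
        code = arr.dtype.str.lstrip("<>|=")
        if code not in _PLY_NAMES:
            arr = arr.astype(np.float64)
            code = "f8"
        fields.append((name, code, arr))

    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {n}"]
    header += [f"property {_PLY_NAMES[code]} {name}" for name, code, _ in fields]
    header.append("end_header")
    header_bytes = ("\n".join(header) + "\n").encode("ascii")

    rec = np.empty(n, dtype=[(name, "<" + code) for name, code, _ in fields])
    for name, _, arr in fields:
        rec[name] = arr

    with open(path, "wb") as fh:
        fh.write(header_bytes)
        if binary:
            fh.write(rec.tobytes())
        else:
            buf = io.StringIO()
            for row in rec:
                buf.write(" ".join(_fmt_ascii(v) for v in row))
                buf.write("\n")
            fh.write(buf.getvalue().encode("ascii"))


def _fmt_ascii(v) -> str:
    if isinstance(v, (np.floating, float)):
        return repr(float(v))
    return str(int(v))


def read_ply(path) -> SemanticPointCloud:
    """Read a PLY cloud, defaulting missing optional channels with a warning.

    Requires at least x, y, z. Missing channels default to density 1.0,
    bud probability 0.0, label -1. Raises :class:`PlyFormatError` naming the
    byte offset on a malformed header or truncated body.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if not data.startswith(b"ply"):
        raise PlyFormatError("not a PLY file: missing 'ply' magic at byte offset 0")
    end = data.find(b"end_header\n")
    if end < 0:
        raise PlyFormatError(f"no end_header found within {len(data)} bytes (offset 0)")
    body_start = end + len(b"end_header\n")
    header_lines = data[:end].decode("ascii", errors="replace").splitlines()

    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for line in header_lines:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise PlyFormatError(
                    f"list vertex properties are unsupported (header before offset {body_start})")
            if tok[1] not in _PLY_DTYPES:
                raise PlyFormatError(
                    f"unknown property type {tok[1]!r} (header before offset {body_start})")
            props.append((tok[2], _PLY_DTYPES[tok[1]]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise PlyFormatError(f"unsupported format {fmt!r} (header before offset {body_start})")
    if n_vertex is None:
        raise PlyFormatError(f"no vertex element declared (header before offset {body_start})")

    dtype = np.dtype([(name, "<" + code) for name, code in props])
    if fmt == "binary_little_endian":
        expected = n_vertex * dtype.itemsize
        if len(data) - body_start < expected:
            raise PlyFormatError(
                f"truncated body: expected {expected} bytes after offset {body_start}, "
                f"file ends at offset {len(data)}")
        rec = np.frombuffer(data, dtype=dtype, count=n_vertex, offset=body_start)
    else:
        text = data[body_start:].decode("ascii", errors="replace")
        rows = text.split()
        need = n_vertex * len(props)
        if len(rows) < need:
            raise PlyFormatError(
                f"truncated ascii body: expected {need} values after offset {body_start}, "
                f"got {len(rows)}")
        flat = np.array(rows[:need], dtype=np.float64).reshape(n_vertex, len(props))
        rec = np.empty(n_vertex, dtype=dtype)
        for j, (name, _) in enumerate(props):
            rec[name] = flat[:, j]

    names = [name for name, _ in props]
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise PlyFormatError(f"missing required property {axis!r} (header before offset {body_start})")
    positions = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(np.float64)

    colors = None
    if all(c in names for c in ("red", "green", "blue")):
        colors = np.column_stack([rec["red"], rec["green"], rec["blue"]]).astype(np.float64) / 255.0

    def _opt(name, default):
        if name in names:
            return np.asarray(rec[name])
        warnings.warn(f"PLY missing {name!r} channel; defaulting to {default}", stacklevel=2)
        return np.full(n_vertex, default)

    density = _opt("density", 1.0)
    semantic = _opt("semantic", 0.0)
    label = _opt("label", -1)
    extras = {name: np.asarray(rec[name]).copy() for name in names if name not in _CANONICAL}
    return SemanticPointCloud(positions=positions, colors=colors,
                              density=np.asarray(density, dtype=np.float64),
                              bud_prob=np.asarray(semantic, dtype=np.float64),
                              label=np.asarray(label).astype(np.int32),
                              extras=extras)
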