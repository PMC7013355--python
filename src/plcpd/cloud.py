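"""Weighted point clouds and their construction from cranium segmentations.

A weighted cloud is an (N, 3) set of world-frame coordinates in mm plus one
membership weight per point in [0, 1].  In the registration model the weights
of the moving cloud (the GMM centroid set) become — after normalization —
the mixture membership priors; the classifier posterior sampled at each
vertex supplies them.

Cloud construction follows the contract "vertices sampling the inner and
outer shell surfaces": boundary voxels of the binary cranium mask (mask minus
its one-voxel erosion), vertex at each boundary voxel centre in world mm,
farthest-point subsampling down to the requested size, and the posterior
volume sampled trilinearly at each vertex as its weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedPointCloud",
    "build_weighted_cloud",
    "read_cloud",
    "write_cloud",
    "farthest_point_subsample",
]


@dataclass
class WeightedPointCloud:
    """Points in mm with per-point membership weights in [0, 1]."""

    points: np.ndarray
    weights: np.ndarray
    source: str | None = field(default=None)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        w = np.asarray(self.weights, dtype=float).reshape(-1)
        if w.shape[0] != pts.shape[0]:
            raise ValueError(
                f"{pts.shape[0]} points but {w.shape[0]} weights"
            )
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        self.points = pts
        self.weights = w

    def __len__(self) -> int:
        return self.points.shape[0]

    def transformed(self, transform) -> "WeightedPointCloud":
        """Cloud with points mapped through a similarity transform."""
        return WeightedPointCloud(
            points=transform.apply(self.points),
            weights=self.weights.copy(),
            source=self.source,
        )


def farthest_point_subsample(
    points: np.ndarray, n: int, seed: int | None = None
) -> np.ndarray:
    """Indices of ``n`` points chosen by greedy farthest-point sampling.

    Deterministic given the seed (which picks the starting point); spreads
    samples evenly over the input, preserving coverage of thin structures.
    """
    pts = np.asarray(points, dtype=float)
    m = pts.shape[0]
    if n >= m:
        return np.arange(m)
    rng = np.random.default_rng(seed)
    chosen = np.empty(n, dtype=np.intp)
    chosen[0] = rng.integers(m)
    dist = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for i in range(1, n):
        chosen[i] = int(np.argmax(dist))
        dist = np.minimum(dist, np.linalg.norm(pts - pts[chosen[i]], axis=1))
    return chosen


def _trilinear_sample(volume: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sample a 3D array at fractional index coordinates (N, 3)."""
    return ndimage.map_coordinates(
        np.asarray(volume, dtype=float), idx.T, order=1, mode="nearest"
    )


def build_weighted_cloud(
    mask: np.ndarray,
    posterior: np.ndarray,
    spacing,
    origin=(0.0, 0.0, 0.0),
    target_points: int = 2000,
    seed: int | None = None,
    source: str | None = None,
) -> WeightedPointCloud:
    """Boundary-voxel cloud of a binary mask, weighted by the posterior.

    Parameters
    ----------
    mask : binary cranium segmentation (True/+1 = cranium).
    posterior : classifier posterior P(cranium | voxel) on the same grid.
    spacing, origin : grid metadata; vertex world position is
        ``origin + index * spacing`` (mm).
    target_points : approximate cloud size after farthest-point subsampling.
    """
    m = np.asarray(mask) > 0
    post = np.asarray(posterior, dtype=float)
    if m.shape != post.shape:
        raise ValueError(f"mask shape {m.shape} != posterior shape {post.shape}")
    if not m.any():
        raise ValueError("empty segmentation: no cranium voxels in mask")
    if target_points < 4:
        raise ValueError(f"target_points must be >= 4, got {target_points}")

    # Shell surfaces = mask voxels lost under one-voxel erosion.
    eroded = ndimage.binary_erosion(m)
    boundary = m & ~eroded
    if not boundary.any():  # mask thinner than 3 voxels everywhere
        boundary = m
    idx = np.argwhere(boundary).astype(float)

    if idx.shape[0] > target_points:
        keep = farthest_point_subsample(idx, target_points, seed=seed)
        idx = idx[keep]

    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.asarray(origin, dtype=float).reshape(3)
    points = origin + idx * spacing
    weights = np.clip(_trilinear_sample(post, idx), 0.0, 1.0)
    return WeightedPointCloud(points=points, weights=weights, source=source)


# --------------------------------------------------------------------- file I/O

_PLY_DTYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
    "short": "<i2", "int16": "<i2", "ushort": "<u2", "uint16": "<u2",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
}


def write_cloud(cloud: WeightedPointCloud, path: str | Path, binary: bool = False) -> None:
    """Write a cloud as PLY (vertex properties x, y, z, weight) or xyzw text.

    The format is chosen from the suffix: ``.ply`` writes PLY (ascii by
    default, binary little-endian when ``binary=True``); anything else writes
    4-column whitespace text.
    """
    path = Path(path)
    n = len(cloud)
    if path.suffix.lower() == ".ply":
        fmt = "binary_little_endian" if binary else "ascii"
        header = (
            "ply\n"
            f"format {fmt} 1.0\n"
            f"element vertex {n}\n"
            "property double x\nproperty double y\nproperty double z\n"
            "property double weight\n"
            "end_header\n"
        )
        rows = np.column_stack([cloud.points, cloud.weights])
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            if binary:
                fh.write(rows.astype("<f8").tobytes())
            else:
                for r in rows:
                    fh.write(f"{r[0]:.10g} {r[1]:.10g} {r[2]:.10g} {r[3]:.10g}\n".encode())
    else:
        np.savetxt(path, np.column_stack([cloud.points, cloud.weights]), fmt="%.10g")


def _read_ply(path: Path) -> WeightedPointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: unexpected end of PLY header")
            tokens = line.decode("ascii", "replace").strip().split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ValueError(f"{path}: list properties on vertices unsupported")
                props.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise ValueError(f"{path}: PLY file has no vertex element")
        names = [p[0] for p in props]
        for coord in ("x", "y", "z"):
            if coord not in names:
                raise ValueError(f"{path}: vertex property {coord!r} missing")
        if fmt == "ascii":
            data = np.empty((n_vertex, len(props)), dtype=float)
            for i in range(n_vertex):
                line = fh.readline()
                vals = line.split()
                if len(vals) < len(props):
                    raise ValueError(
                        f"{path}: malformed vertex line {i + 1}: {line!r}"
                    )
                data[i] = [float(v) for v in vals[: len(props)]]
            cols = {name: data[:, j] for j, (name, _) in enumerate(props)}
        else:
            dtype = np.dtype([(name, _PLY_DTYPES[typ]) for name, typ in props])
            raw = fh.read(dtype.itemsize * n_vertex)
            if len(raw) < dtype.itemsize * n_vertex:
                raise ValueError(f"{path}: truncated binary vertex data")
            rec = np.frombuffer(raw, dtype=dtype, count=n_vertex)
            cols = {name: rec[name].astype(float) for name, _ in props}
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    if "weight" in cols:
        weights = cols["weight"]
    else:
        logger.info("%s: no 'weight' vertex property; defaulting weights to 1", path)
        weights = np.ones(n_vertex)
    return WeightedPointCloud(points=points, weights=weights, source=str(path))


def read_cloud(path: str | Path) -> WeightedPointCloud:
    """Read a PLY (ascii or binary little-endian) or whitespace xyz[w] cloud.

    A missing weight column/property defaults every weight to 1 with a logged
    notice.
    """
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return _read_ply(path)
    rows = []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            vals = stripped.split()
            if ncol is None:
                if len(vals) not in (3, 4):
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 or 4 columns, got {len(vals)}"
                    )
                ncol = len(vals)
            if len(vals) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncol} columns, got {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable value ({exc})") from None
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{path}: no points found")
    if ncol == 3:
        logger.info("%s: 3-column file; defaulting weights to 1", path)
        weights = np.ones(arr.shape[0])
    else:
        weights = arr[:, 3]
    return WeightedPointCloud(points=arr[:, :3], weights=weights, source=str(path))


def hausdorff_points(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets (mm)."""
    ta, tb = cKDTree(a), cKDTree(b)
    return float(max(tb.query(a)[0].max(), ta.query(b)[0].max()))
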