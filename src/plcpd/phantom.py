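"""Synthetic ultrasound fetal-head phantoms with known ground truth.

Clinical 3D fetal ultrasound pairs are not redistributable, so every other
module is exercised on phantoms generated here: an ellipsoidal cranium shell
embedded in soft tissue and background, corrupted by correlated
multiplicative speckle, with angular occlusion sectors emulating the
acoustic shadows cast by non-uniform cranial calcification.  A pair of
"acquisitions" shares the same anatomy related by a known similarity
transform, but each member carries its own occlusion sectors (complementary
missing data, as real axial/coronal projections do) and an independent
speckle realization.

Occlusion sectors are azimuthal wedges about the beam axis, anchored at the
ellipsoid centre: a wedge of angular width Δ removes ≈ Δ/360 of the shell.
Shell intensities inside a wedge are multiplied by the sector's attenuation
factor and the corresponding label voxels are dropped (the signal is lost).

Speckle is a multiplicative Rayleigh field (unit mean after normalization)
smoothed with a small Gaussian kernel so that neighbouring voxels are
correlated, the standard minimal model of fully developed speckle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .cloud import WeightedPointCloud
from .transform import SimilarityTransform, random_similarity
from .volume import Volume3D

__all__ = [
    "OcclusionSector",
    "PhantomSpec",
    "make_phantom_pair",
    "make_cloud_pair",
    "sample_shell_surface",
]

_BEAM_AXIS = 2  # sound propagates along the volume's last axis


@dataclass(frozen=True)
class OcclusionSector:
    """Azimuthal shadow wedge about the beam axis.

    ``direction`` fixes the wedge's central azimuth (only its component in
    the plane perpendicular to the beam axis matters); ``width_deg`` its
    angular width; shell intensities inside are multiplied by ``factor``.
    """

    direction: tuple[float, float, float]
    width_deg: float
    factor: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.width_deg <= 360.0:
            raise ValueError(f"angular width must lie in (0, 360], got {self.width_deg}")
        if not 0.0 <= self.factor < 1.0:
            raise ValueError(f"attenuation factor must lie in [0, 1), got {self.factor}")

    def contains(self, rel: np.ndarray) -> np.ndarray:
        """Boolean mask of relative positions (…, 3) inside the wedge."""
        d = np.asarray(self.direction, dtype=float)
        u, v = [i for i in range(3) if i != _BEAM_AXIS]
        az0 = np.arctan2(d[v], d[u])
        az = np.arctan2(rel[..., v], rel[..., u])
        diff = np.angle(np.exp(1j * (az - az0)))
        return np.abs(diff) <= np.radians(self.width_deg) / 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom pair; the seed fixes all randomness."""

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)  # mm
    semi_axes: tuple[float, float, float] = (28.0, 24.0, 20.0)  # mm
    shell_thickness: float = 2.5  # mm
    center: tuple[float, float, float] | None = None  # mm; None = grid centre
    background_intensity: float = 30.0
    interior_intensity: float = 90.0
    shell_intensity: float = 200.0
    speckle: float = 1.0  # Rayleigh scale; 0 disables speckle
    speckle_smooth_vox: float = 0.8  # Gaussian sigma of speckle correlation
    sectors_a: tuple[OcclusionSector, ...] = ()
    sectors_b: tuple[OcclusionSector, ...] = ()
    transform: SimilarityTransform | None = None  # truth mapping B-frame → A-frame
    seed: int = 0

    def __post_init__(self) -> None:
        ax = np.asarray(self.semi_axes, dtype=float)
        if not (np.all(ax > self.shell_thickness) and self.shell_thickness > 0):
            raise ValueError("need semi-axes > shell thickness > 0")
        extent = np.asarray(self.shape) * np.asarray(self.spacing)
        c = np.asarray(self.center_mm)
        if np.any(c - ax < 0) or np.any(c + ax > extent):
            raise ValueError(
                f"ellipsoid (semi-axes {tuple(ax)} mm about {tuple(c)} mm) "
                f"exceeds the {tuple(extent)} mm grid"
            )

    @property
    def center_mm(self) -> tuple[float, float, float]:
        if self.center is not None:
            return self.center
        extent = np.asarray(self.shape) * np.asarray(self.spacing)
        return tuple(extent / 2.0)

    @property
    def truth(self) -> SimilarityTransform:
        return self.transform if self.transform is not None else SimilarityTransform.identity()

    def with_transform(self, transform: SimilarityTransform) -> "PhantomSpec":
        return replace(self, transform=transform)


def _world_grid(spec: PhantomSpec) -> np.ndarray:
    """(X, Y, Z, 3) world coordinates of every voxel centre, origin at 0."""
    axes = [
        np.arange(n, dtype=float) * s
        for n, s in zip(spec.shape, spec.spacing)
    ]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _anatomy(spec: PhantomSpec, world: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless intensity field and shell mask at given world positions."""
    rel = world - np.asarray(spec.center_mm)
    ax_out = np.asarray(spec.semi_axes, dtype=float)
    ax_in = ax_out - spec.shell_thickness
    rho_out = np.sqrt(((rel / ax_out) ** 2).sum(axis=-1))
    rho_in = np.sqrt(((rel / ax_in) ** 2).sum(axis=-1))
    interior = rho_in < 1.0
    shell = (rho_out <= 1.0) & ~interior
    intensity = np.full(world.shape[:-1], spec.background_intensity)
    intensity[interior] = spec.interior_intensity
    intensity[shell] = spec.shell_intensity
    return intensity, shell


def _apply_occlusion(
    intensity: np.ndarray,
    shell: np.ndarray,
    rel: np.ndarray,
    sectors: tuple[OcclusionSector, ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Attenuate shell intensities inside wedges; drop their labels."""
    labels = shell.copy()
    out = intensity.copy()
    for sec in sectors:
        hit = shell & sec.contains(rel)
        out[hit] = out[hit] * sec.factor
        labels[hit] = False
    return out, labels


def _speckle_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Correlated multiplicative speckle, normalized to unit mean."""
    if spec.speckle <= 0:
        return np.ones(spec.shape)
    raw = rng.rayleigh(scale=spec.speckle, size=spec.shape)
    smooth = ndimage.gaussian_filter(raw, sigma=spec.speckle_smooth_vox)
    return smooth / smooth.mean()


def make_phantom_pair(
    spec: PhantomSpec,
) -> tuple[Volume3D, Volume3D, np.ndarray, np.ndarray, SimilarityTransform]:
    """Generate the two simulated acquisitions of one phantom.

    Returns ``(vol_a, vol_b, labels_a, labels_b, truth)`` where the truth
    transform maps B-frame world coordinates onto the A frame
    (``p_A = 𝒯(p_B)``); labels are boolean shell masks with occluded shell
    voxels excluded.  Acquisition B is the trilinear resampling of A's
    noiseless anatomy under the truth transform, with its own occlusion
    sectors and an independent speckle realization.
    """
    rng = np.random.default_rng(spec.seed)
    truth = spec.truth
    world = _world_grid(spec)
    center = np.asarray(spec.center_mm)

    # Acquisition A: anatomy evaluated on its own grid.
    anat_a, shell_a = _anatomy(spec, world)
    int_a, labels_a = _apply_occlusion(anat_a, shell_a, world - center, spec.sectors_a)
    vol_a = int_a * _speckle_field(spec, rng)

    # Acquisition B: A's noiseless anatomy resampled at 𝒯(p_B).
    flat_b = world.reshape(-1, 3)
    mapped = truth.apply(flat_b)
    idx = (mapped / np.asarray(spec.spacing)).T
    anat_b = ndimage.map_coordinates(
        anat_a, idx, order=1, mode="constant", cval=spec.background_intensity
    ).reshape(spec.shape)
    # Shell membership in the B frame is exact (analytic at the mapped point).
    rel_mapped = (mapped - center).reshape(spec.shape + (3,))
    ax_out = np.asarray(spec.semi_axes, dtype=float)
    ax_in = ax_out - spec.shell_thickness
    rho_out = np.sqrt(((rel_mapped / ax_out) ** 2).sum(axis=-1))
    rho_in = np.sqrt(((rel_mapped / ax_in) ** 2).sum(axis=-1))
    shell_b = (rho_out <= 1.0) & (rho_in >= 1.0)
    center_b = truth.inverse().apply(center[None, :])[0]
    int_b, labels_b = _apply_occlusion(
        anat_b, shell_b, world - center_b, spec.sectors_b
    )
    vol_b = int_b * _speckle_field(spec, rng)

    spacing = tuple(float(s) for s in spec.spacing)
    return (
        Volume3D(vol_a, spacing=spacing),
        Volume3D(vol_b, spacing=spacing),
        labels_a,
        labels_b,
        truth,
    )


def sample_shell_surface(
    spec: PhantomSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample n points on the shell's inner and outer ellipsoid surfaces.

    Directions are uniform on the sphere; each is projected radially onto
    the inner or outer surface (half each), in A-frame world mm.
    """
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    ax_out = np.asarray(spec.semi_axes, dtype=float)
    ax_in = ax_out - spec.shell_thickness
    axes = np.where(np.arange(n)[:, None] % 2 == 0, ax_out, ax_in)
    r = 1.0 / np.sqrt(((u / axes) ** 2).sum(axis=1))
    return np.asarray(spec.center_mm) + u * r[:, None]


def make_cloud_pair(
    spec: PhantomSpec,
    n_points: int = 1000,
    outlier_fraction: float = 0.0,
    inlier_weight: float = 0.95,
    outlier_weight: float = 0.01,
    weight_noise: float = 0.0,
    inlier_weight_floor: float = 0.5,
    position_noise_mm: float = 0.5,
) -> tuple[WeightedPointCloud, WeightedPointCloud, SimilarityTransform]:
    """Shell-surface cloud pair with optional outliers and weight noise.

    Returns ``(fixed, moving, truth)``.  One pool of shell-surface samples
    (the shared anatomy) is drawn in the A frame; each cloud keeps the
    samples that survive its own acquisition's occlusion sectors, and the
    moving cloud is carried to the B frame by the inverse truth transform.
    Without occlusion or noise the clouds therefore correspond point-to-point
    through the truth transform.  ``outlier_fraction`` of the moving cloud's
    points (an exact, deterministic count) are replaced by points uniform in
    the cloud's bounding box carrying ``outlier_weight``; inlier weights are
    ``inlier_weight``, beta-perturbed when ``weight_noise > 0`` and clipped
    to ``[inlier_weight_floor, 1]``.
    """
    if not 0.0 <= outlier_fraction < 1.0:
        raise ValueError(f"outlier fraction must lie in [0, 1), got {outlier_fraction}")
    rng = np.random.default_rng(spec.seed)
    truth = spec.truth

    def occlude(points_frame: np.ndarray, center: np.ndarray, sectors) -> np.ndarray:
        keep = np.ones(points_frame.shape[0], dtype=bool)
        for sec in sectors:
            keep &= ~sec.contains(points_frame - center)
        return keep

    center_a = np.asarray(spec.center_mm)
    center_b = truth.inverse().apply(center_a[None, :])[0]
    n_out = int(round(outlier_fraction * n_points))
    n_in = n_points - n_out

    # Shared surface-sample pool, grown until both occlusion filters retain
    # enough points; each cloud keeps its own survivors.
    pool = np.empty((0, 3))
    while True:
        pool = np.vstack([pool, sample_shell_surface(spec, max(2 * n_points, 64), rng)])
        keep_a = occlude(pool, center_a, spec.sectors_a)
        pool_b = truth.inverse().apply(pool)
        keep_b = occlude(pool_b, center_b, spec.sectors_b)
        if keep_a.sum() >= n_points and keep_b.sum() >= n_in:
            break
    pts_a = pool[keep_a][:n_points]
    pts_b = pool_b[keep_b][:n_in]

    def inlier_weights(n_req: int) -> np.ndarray:
        if weight_noise <= 0:
            return np.full(n_req, inlier_weight)
        kappa = 1.0 / weight_noise
        w = rng.beta(inlier_weight * kappa, (1.0 - inlier_weight) * kappa, size=n_req)
        return np.clip(w, inlier_weight_floor, 1.0)

    # Fixed cloud (A frame): inliers only.
    if position_noise_mm > 0:
        pts_a = pts_a + rng.normal(scale=position_noise_mm, size=pts_a.shape)
    fixed = WeightedPointCloud(pts_a, inlier_weights(n_points), source="phantom-A")

    # Moving cloud (B frame): inliers plus an exact count of box outliers.
    if position_noise_mm > 0:
        pts_b = pts_b + rng.normal(scale=position_noise_mm, size=pts_b.shape)
    w_b = inlier_weights(n_in)
    if n_out > 0:
        lo = pts_b.min(axis=0)
        hi = pts_b.max(axis=0)
        pad = 0.1 * (hi - lo)
        outliers = rng.uniform(lo - pad, hi + pad, size=(n_out, 3))
        pts_b = np.vstack([pts_b, outliers])
        w_b = np.concatenate([w_b, np.full(n_out, outlier_weight)])
    moving = WeightedPointCloud(pts_b, w_b, source="phantom-B")
    return fixed, moving, truth


def sample_pair_spec(
    seed: int,
    base: PhantomSpec | None = None,
    max_rotation_deg: float = 40.0,
    max_translation_mm: float = 20.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
) -> PhantomSpec:
    """Spec with a seed-sampled ground-truth transform (rotation ≤ 40°,
    |t| ≤ 20 mm, scale in [0.9, 1.1] by default)."""
    rng = np.random.default_rng(seed)
    truth = random_similarity(
        rng,
        max_rotation_deg=max_rotation_deg,
        max_translation_mm=max_translation_mm,
        scale_range=scale_range,
    )
    spec = base if base is not None else PhantomSpec()
    return replace(spec, transform=truth, seed=seed)
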