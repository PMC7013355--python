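"""Similarity transforms in 3D: x' = s·R·x + t.

The registration engine estimates a similarity transform (rotation R,
isotropic scale s, translation t, all in the world/mm frame).  This module
holds the transform type, composition/inversion algebra, Euler-angle
decomposition (used for rotation-error reporting) and JSON (de)serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["SimilarityTransform", "random_similarity"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class SimilarityTransform:
    """Rigid-plus-scale map ``x' = s * R @ x + t`` (millimetres).

    Parameters
    ----------
    rotation : (3, 3) proper orthonormal matrix.
    scale : positive isotropic scale factor.
    translation : (3,) offset in mm.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    scale: float = 1.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        s = float(self.scale)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal (R^T R = I)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det(R) = +1)")
        if s <= 0:
            raise ValueError(f"scale must be positive, got {s}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "scale", s)
        object.__setattr__(self, "translation", t)

    # ------------------------------------------------------------------ algebra
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of points through the transform."""
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation.T + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return ``self ∘ other`` (apply *other* first, then *self*)."""
        return SimilarityTransform(
            rotation=self.rotation @ other.rotation,
            scale=self.scale * other.scale,
            translation=self.scale * self.rotation @ other.translation
            + self.translation,
        )

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        sinv = 1.0 / self.scale
        return SimilarityTransform(
            rotation=Rinv, scale=sinv, translation=-sinv * Rinv @ self.translation
        )

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    # ------------------------------------------------------------- decomposition
    def euler_angles(self, convention: str = "ZYX") -> np.ndarray:
        """Rotation as intrinsic Euler angles in degrees (default Z-Y-X)."""
        return Rotation.from_matrix(self.rotation).as_euler(convention, degrees=True)

    def rotation_angle(self) -> float:
        """Total rotation magnitude in degrees (axis-angle norm)."""
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    # --------------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "scale": self.scale,
            "translation": self.translation.tolist(),
            "convention": "x' = s*R*x + t, mm, world frame",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            rotation=np.asarray(d["rotation"], dtype=float),
            scale=float(d["scale"]),
            translation=np.asarray(d["translation"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SimilarityTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def random_similarity(
    rng: np.random.Generator,
    max_rotation_deg: float = 40.0,
    max_translation_mm: float = 20.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
) -> SimilarityTransform:
    """Draw a random similarity transform.

    The rotation axis is uniform on the sphere and the rotation angle uniform
    in ``[0, max_rotation_deg]``; the translation is uniform in the cube of
    half-width ``max_translation_mm``; the scale uniform in ``scale_range``.
    """
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    s = rng.uniform(*scale_range)
    return SimilarityTransform(rotation=R, scale=s, translation=t)
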