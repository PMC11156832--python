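"""Closed-form rigid (6 degrees-of-freedom) transform algebra and resampling.

Conventions
-----------
A :class:`RigidTransform` acts on world coordinates (mm) as

    T(p) = R (p - c) + c + t

with rotation matrix ``R``, rotation center ``c`` and translation ``t``.
``resample_*`` functions interpret the transform as the physical motion of
the source object: the output voxel at world position ``x`` takes the source
value at ``T^{-1}(x)``. Composition and inversion are exact closed forms on
the homogeneous 4x4 representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volume import Volume3D

__all__ = ["RigidTransform", "compose", "invert", "resample_linear", "resample_nn"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform: rotation about a center, then translation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))  # 3x3, det +1
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        R = self.rotation
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler_deg(
        cls,
        angles_deg: tuple[float, float, float],
        translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
        center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Build from extrinsic x-y-z Euler angles in degrees."""
        R = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
        return cls(rotation=R, translation=np.asarray(translation, float), center=np.asarray(center, float))

    @classmethod
    def from_matrix(cls, homogeneous: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (center set to the origin)."""
        H = np.asarray(homogeneous, dtype=float)
        if H.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(rotation=H[:3, :3], translation=H[:3, 3], center=np.zeros(3))

    # -- views ------------------------------------------------------------
    def euler_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_euler("xyz", degrees=True)

    def rotation_angle_deg(self) -> float:
        """Total rotation angle (magnitude of the rotation vector), degrees."""
        return float(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec(degrees=True)))

    def effective_translation(self) -> np.ndarray:
        """Translation part of the centered form re-expressed about the origin."""
        return self.as_matrix()[:3, 3]

    def as_matrix(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = self.rotation
        H[:3, 3] = self.translation + self.center - self.rotation @ self.center
        return H

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to (N, 3) world points (a single point is also accepted)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = (pts - self.center) @ self.rotation.T + self.center + self.translation
        return out[0] if single else out

    def is_identity(self, atol: float = 1e-12) -> bool:
        H = self.as_matrix()
        return bool(np.allclose(H, np.eye(4), atol=atol))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "angles_deg": [float(a) for a in self.euler_deg()],
            "translation_mm": [float(t) for t in self.translation],
            "center_mm": [float(c) for c in self.center],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls.from_euler_deg(
            tuple(d["angles_deg"]), tuple(d["translation_mm"]), tuple(d.get("center_mm", (0, 0, 0)))
        )


def compose(first: RigidTransform, second: RigidTransform) -> RigidTransform:
    """The transform whose action equals applying ``first`` then ``second``."""
    return RigidTransform.from_matrix(second.as_matrix() @ first.as_matrix())


def invert(t: RigidTransform) -> RigidTransform:
    """Exact closed-form inverse: R^T and the matching translation."""
    Rinv = t.rotation.T
    H = t.as_matrix()
    Hinv = np.eye(4)
    Hinv[:3, :3] = Rinv
    Hinv[:3, 3] = -Rinv @ H[:3, 3]
    return RigidTransform.from_matrix(Hinv)


def _index_map(source: Volume3D, transform: RigidTransform, reference: Volume3D):
    """matrix, offset mapping reference voxel indices to source voxel indices."""
    M = np.linalg.inv(source.affine) @ np.linalg.inv(transform.as_matrix()) @ reference.affine
    return M[:3, :3], M[:3, 3]


def resample_linear(source: Volume3D, transform: RigidTransform, reference: Volume3D) -> Volume3D:
    """Trilinear resampling of ``source`` moved by ``transform`` onto the
    reference grid. Out-of-field voxels are 0."""
    matrix, offset = _index_map(source, transform, reference)
    data = ndimage.affine_transform(
        np.asarray(source.data, dtype=float),
        matrix,
        offset=offset,
        output_shape=reference.shape,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return Volume3D(data=data, voxel_size=reference.voxel_size, affine=reference.affine.copy())


def resample_nn(source: Volume3D, transform: RigidTransform, reference: Volume3D) -> Volume3D:
    """Nearest-neighbour resampling: every output voxel is an exact member of
    the source value set (or 0 outside the field), so labels and binary
    masks survive without interpolation smoothing."""
    matrix, offset = _index_map(source, transform, reference)
    data = ndimage.affine_transform(
        np.asarray(source.data),
        matrix,
        offset=offset,
        output_shape=reference.shape,
        order=0,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return Volume3D(data=data, voxel_size=reference.voxel_size, affine=reference.affine.copy())
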