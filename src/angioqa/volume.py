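"""Core image containers shared by every analysis stage.

``Volume3D`` is the unit all 3-D stages exchange: a scalar voxel grid with a
physical voxel size (mm) and a 4x4 world affine mapping voxel indices to
world coordinates (mm, RAS-like axes, 0-based indices, voxel-center
convention). ``Image2D`` is its 2-D counterpart for projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "Image2D", "read_nifti", "write_nifti", "write_png", "read_image"]


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class Volume3D:
    """A 3-D scalar grid with physical geometry.

    Parameters
    ----------
    data
        Array of shape (nx, ny, nz); axis order matches the first three world
        axes of ``affine``.
    voxel_size
        Physical voxel edge lengths in mm, one per data axis.
    affine
        4x4 voxel-index -> world-mm transform. Defaults to a diagonal affine
        built from ``voxel_size`` with the origin at voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D.data must be 3-D, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size components must be > 0, got {self.voxel_size}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D.data must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (may be fractional) to world mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def copy_with(self, data: np.ndarray) -> "Volume3D":
        """Same geometry, new data."""
        return Volume3D(data=data, voxel_size=self.voxel_size, affine=self.affine.copy())


@dataclass
class Image2D:
    """A 2-D scalar grid with in-plane pixel size (mm)."""

    data: np.ndarray
    pixel_size: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"Image2D.data must be 2-D, got shape {self.data.shape}")
        self.pixel_size = tuple(float(v) for v in self.pixel_size)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Image2D.data must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


def read_nifti(path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data=data, voxel_size=tuple(float(z) for z in zooms), affine=np.asarray(img.affine))


def write_nifti(volume: Volume3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))


def write_png(image: Image2D, path) -> None:
    """Save as 16-bit grayscale PNG, linearly rescaled to the full range."""
    import imageio.v3 as iio

    arr = np.asarray(image.data, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    scaled = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)
    iio.imwrite(str(path), np.round(scaled * 65535).astype(np.uint16))


def read_image(path, pixel_size: tuple[float, float] = (1.0, 1.0)) -> Image2D:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)), dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    return Image2D(data=arr, pixel_size=pixel_size)
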