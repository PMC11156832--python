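"""Digital vascular phantom: bright tubular vessels on a suppressed background.

The phantom emulates the data the downstream analysis assumes: a branching
tree of tubes spanning calibers from large trunk vessels (~4 mm diameter)
down to perforator-scale twigs (<0.3 mm), rasterized onto voxel grids of
configurable resolution, with repeat "acquisitions" that differ only by
independent additive Gaussian noise and, optionally, a small rigid
misalignment. A 2-D projection pipeline renders a geometrically perturbed
angiogram-like partner image standing in for a second modality.

Noise is additive Gaussian rather than Rician: the difference-method noise
estimator assumes noise cancels symmetrically in A - B, and the Gaussian
model keeps every recovery oracle closed-form. This is a documented
limitation relative to magnitude MR data at low SNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rigid import RigidTransform, resample_linear
from .volume import Image2D, Volume3D

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "VesselTree",
    "PhantomSpec",
    "AcquisitionPair",
    "CALIBER_RADIUS_BOUNDS",
    "caliber_class_for_radius",
    "build_vessel_tree",
    "rasterize",
    "add_noise",
    "make_pair",
    "project_dsa_like",
]

#: Disjoint, ordered radius ranges (mm) defining the caliber taxonomy:
#: carotid-siphon/basilar scale, M1/A1/P1 scale, M2/A2/P2 scale, perforators.
CALIBER_RADIUS_BOUNDS = {
    "large": (1.0, np.inf),
    "medium": (0.4, 1.0),
    "small": (0.15, 0.4),
    "perforator": (0.0, 0.15),
}

_AXIS_INDEX = {"axial": 2, "coronal": 1, "sagittal": 0}


def caliber_class_for_radius(radius: float) -> str:
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    for name, (lo, hi) in CALIBER_RADIUS_BOUNDS.items():
        if lo <= radius < hi or (name == "large" and radius >= lo):
            return name
    raise AssertionError("unreachable: caliber ranges cover (0, inf)")


@dataclass(frozen=True)
class Segment:
    """A straight tube with hemispherical caps (a capsule)."""

    start: tuple[float, float, float]  # mm, world coordinates
    end: tuple[float, float, float]
    radius: float  # mm
    caliber_class: str
    level: int  # branching depth, 0 = trunk
    parent: int | None  # index of parent segment, None for the root

    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))


@dataclass
class VesselTree:
    segments: list[Segment]
    seed: int

    def __post_init__(self) -> None:
        for i, seg in enumerate(self.segments):
            if seg.radius <= 0:
                raise ValueError(f"segment {i} has non-positive radius {seg.radius}")
        for i, seg in enumerate(self.segments):
            if seg.parent is not None:
                parent = self.segments[seg.parent]
                if _point_segment_distance(np.asarray(seg.start), parent) > 1e-9:
                    raise ValueError(f"segment {i} does not start on its parent")

    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.segments])

    def caliber_classes(self) -> set[str]:
        return {s.caliber_class for s in self.segments}

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "segments": [
                {
                    "start": list(s.start),
                    "end": list(s.end),
                    "radius": s.radius,
                    "caliber_class": s.caliber_class,
                    "level": s.level,
                    "parent": s.parent,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VesselTree":
        segs = [
            Segment(
                start=tuple(s["start"]),
                end=tuple(s["end"]),
                radius=float(s["radius"]),
                caliber_class=s["caliber_class"],
                level=int(s["level"]),
                parent=s["parent"],
            )
            for s in d["segments"]
        ]
        return cls(segments=segs, seed=int(d["seed"]))


@dataclass
class PhantomSpec:
    """Rasterization grid and intensity model for one acquisition regime.

    Default intensities (vessel 300, background 60) with the default noise
    sigma of 10 put the contrast-to-noise ratio in the single digits, the
    regime the analysis operates in; they are configuration, not claims
    about any scanner.
    """

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]  # mm
    vessel_intensity: float = 300.0
    background_intensity: float = 60.0
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        # equality is allowed as the degenerate zero-contrast phantom used in
        # null tests; vessels can never be darker than background
        if not (self.vessel_intensity >= self.background_intensity >= 0):
            raise ValueError(
                "require vessel_intensity >= background_intensity >= 0, got "
                f"{self.vessel_intensity}, {self.background_intensity}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size components must be > 0, got {self.voxel_size}")


@dataclass
class AcquisitionPair:
    """Two co-acquired volumes differing only by independent noise
    (and optionally a recorded rigid misalignment of the second)."""

    volume_a: Volume3D
    volume_b: Volume3D
    true_misalignment: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        if self.volume_a.shape != self.volume_b.shape:
            raise ValueError("pair volumes must share grid_shape")
        if self.volume_a.voxel_size != self.volume_b.voxel_size:
            raise ValueError("pair volumes must share voxel_size")


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotate_towards(direction: np.ndarray, angle_deg: float, azimuth_deg: float) -> np.ndarray:
    """Tilt ``direction`` by ``angle_deg`` around it, at the given azimuth."""
    d = _unit(direction)
    # build an orthonormal frame around d
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, helper))
    v = np.cross(d, u)
    a = np.deg2rad(angle_deg)
    b = np.deg2rad(azimuth_deg)
    return _unit(np.cos(a) * d + np.sin(a) * (np.cos(b) * u + np.sin(b) * v))


def build_vessel_tree(
    seed: int,
    n_branch_levels: int,
    extent_mm: tuple[float, float, float] = (40.0, 40.0, 28.0),
    trunk_radius: float = 2.0,
) -> VesselTree:
    """Grow a deterministic bifurcating tree of tube segments.

    Radii halve per branching level, so with the default trunk radius of
    2 mm a five-level tree spans diameters 4 mm down to 0.25 mm and covers
    every caliber class (large, medium, small, perforator). Each child
    segment starts exactly at its parent's endpoint.
    """
    if n_branch_levels < 1:
        raise ValueError(f"n_branch_levels must be >= 1, got {n_branch_levels}")
    rng = np.random.default_rng(seed)
    extent = np.asarray(extent_mm, dtype=float)
    margin = 2.5

    trunk_len = 0.35 * extent[2]
    start = np.array([0.5 * extent[0], 0.5 * extent[1], margin])
    direction = _unit(np.array([0.12, -0.08, 1.0]))
    segments: list[Segment] = [
        Segment(
            start=tuple(start),
            end=tuple(start + trunk_len * direction),
            radius=trunk_radius,
            caliber_class=caliber_class_for_radius(trunk_radius),
            level=0,
            parent=None,
        )
    ]
    frontier = [0]
    for level in range(1, n_branch_levels):
        radius = trunk_radius * 0.5**level
        length = max(trunk_len * 0.72**level, 8.0 * radius)
        new_frontier: list[int] = []
        for parent_idx in frontier:
            parent = segments[parent_idx]
            pdir = _unit(np.subtract(parent.end, parent.start))
            base_azimuth = rng.uniform(0.0, 360.0)
            for k in range(2):
                angle = rng.uniform(25.0, 45.0)
                azimuth = base_azimuth + 180.0 * k + rng.uniform(-20.0, 20.0)
                cdir = _rotate_towards(pdir, angle, azimuth)
                cstart = np.asarray(parent.end)
                cend = cstart + length * cdir
                # keep endpoints inside the phantom extent
                cend = np.clip(cend, margin, extent - margin)
                if np.linalg.norm(cend - cstart) < 2.0 * radius:
                    cend = np.clip(cstart + 4.0 * radius * cdir, 0.5, extent - 0.5)
                segments.append(
                    Segment(
                        start=tuple(cstart),
                        end=tuple(cend),
                        radius=radius,
                        caliber_class=caliber_class_for_radius(radius),
                        level=level,
                        parent=parent_idx,
                    )
                )
                new_frontier.append(len(segments) - 1)
        frontier = new_frontier
    return VesselTree(segments=segments, seed=seed)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _point_segment_distance(points: np.ndarray, seg: Segment) -> np.ndarray:
    """Euclidean distance from (N, 3) points (or a single point) to a segment."""
    pts = np.atleast_2d(points)
    a = np.asarray(seg.start, dtype=float)
    b = np.asarray(seg.end, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        d = np.linalg.norm(pts - a, axis=1)
    else:
        t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
        d = np.linalg.norm(pts - a - t[:, None] * ab, axis=1)
    return d if points.ndim > 1 else d[0]


def vessel_fraction(tree: VesselTree, spec: PhantomSpec, subsamples: int = 8) -> np.ndarray:
    """Per-voxel in-tube volume fraction in [0, 1].

    Voxels whose center is further than half a voxel diagonal from every tube
    surface are resolved analytically (fraction 0 or 1); voxels in the
    boundary band are estimated by ``subsamples``^3 regular subsampling
    (midpoint rule), the deterministic partial-volume model used throughout.
    """
    vs = np.asarray(spec.voxel_size, dtype=float)
    shape = tuple(int(s) for s in spec.grid_shape)
    half_diag = 0.5 * float(np.linalg.norm(vs))
    frac = np.zeros(shape, dtype=float)

    # midpoint-rule subsample offsets within a voxel, in index units
    offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)

    for seg in tree.segments:
        if 2.0 * seg.radius < max(vs):
            logger.warning(
                "segment radius %.3f mm is under half the largest voxel dimension "
                "(%.3f mm): strong partial-volume averaging expected",
                seg.radius,
                max(vs),
            )
        lo_w = np.minimum(seg.start, seg.end) - (seg.radius + half_diag)
        hi_w = np.maximum(seg.start, seg.end) + (seg.radius + half_diag)
        lo = np.maximum(np.floor(lo_w / vs).astype(int), 0)
        hi = np.minimum(np.ceil(hi_w / vs).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        centers = idx * vs  # default diagonal affine: world = index * voxel_size
        d = _point_segment_distance(centers, seg)
        inside = d <= seg.radius - half_diag
        band = (~inside) & (d < seg.radius + half_diag)
        seg_frac = inside.astype(float)
        if np.any(band):
            band_centers = centers[band]
            pts = band_centers[:, None, :] + sub[None, :, :] * vs[None, None, :]
            dsub = _point_segment_distance(pts.reshape(-1, 3), seg).reshape(len(band_centers), -1)
            seg_frac[band] = (dsub <= seg.radius).mean(axis=1)
        flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), shape)
        # overlapping tubes (e.g. at bifurcations) take the max fraction
        np.maximum.at(frac.reshape(-1), flat, seg_frac)
    return frac


def rasterize(tree: VesselTree, spec: PhantomSpec, subsamples: int = 8) -> Volume3D:
    """Render the tree onto the grid: vessel intensity inside tubes,
    background outside, partial-volume blend on the boundary. No noise."""
    if not tree.segments:
        raise ValueError("cannot rasterize an empty tree")
    frac = vessel_fraction(tree, spec, subsamples=subsamples)
    data = spec.background_intensity + (spec.vessel_intensity - spec.background_intensity) * frac
    return Volume3D(data=data, voxel_size=spec.voxel_size)


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------

def add_noise(volume: Volume3D, sigma: float, seed: int) -> Volume3D:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return volume.copy_with(volume.data.copy())
    rng = np.random.default_rng(seed)
    return volume.copy_with(volume.data + rng.normal(0.0, sigma, size=volume.shape))


def make_pair(
    clean: Volume3D,
    sigma: float,
    seed_a: int,
    seed_b: int,
    misalignment: RigidTransform | None = None,
) -> AcquisitionPair:
    """Simulate a repeat-acquisition couple (A, B).

    A is the clean volume plus noise(seed_a); B is the clean volume moved by
    ``misalignment`` (linear interpolation) plus independent noise(seed_b).
    The true misalignment is recorded so registration accuracy can be scored.
    """
    if seed_a == seed_b:
        raise ValueError("seed_a must differ from seed_b (noise must be independent)")
    misalignment = misalignment if misalignment is not None else RigidTransform.identity()
    volume_a = add_noise(clean, sigma, seed_a)
    moved = clean if misalignment.is_identity() else resample_linear(clean, misalignment, clean)
    volume_b = add_noise(moved, sigma, seed_b)
    return AcquisitionPair(volume_a=volume_a, volume_b=volume_b, true_misalignment=misalignment)


# ---------------------------------------------------------------------------
# modality-partner projection
# ---------------------------------------------------------------------------

def project_dsa_like(
    volume: Volume3D,
    axis: str = "axial",
    rotation_deg: float = 0.0,
    blur_sigma_px: float = 0.0,
    intensity_gamma: float = 1.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> Image2D:
    """Render a same-vessels, different-modality partner image.

    Maximum-intensity projection along ``axis``, then in-plane rotation,
    Gaussian blur, gamma remapping of the [0, 1]-normalized intensities, and
    mild additive noise. With rotation 0, blur 0, gamma 1 and noise 0 the
    output is the plain MIP (normalized to [0, 1]).
    """
    from scipy import ndimage

    if blur_sigma_px < 0:
        raise ValueError(f"blur_sigma_px must be >= 0, got {blur_sigma_px}")
    if intensity_gamma <= 0:
        raise ValueError(f"intensity_gamma must be > 0, got {intensity_gamma}")
    ax = _AXIS_INDEX[axis]
    img = np.asarray(volume.data).max(axis=ax).astype(float)
    lo, hi = float(img.min()), float(img.max())
    img = np.zeros_like(img) if hi <= lo else (img - lo) / (hi - lo)
    if rotation_deg % 360.0 != 0.0:
        img = ndimage.rotate(img, rotation_deg, reshape=False, order=1, mode="constant", cval=0.0)
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    img = np.clip(img, 0.0, 1.0) ** intensity_gamma
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    pix = tuple(v for i, v in enumerate(volume.voxel_size) if i != ax)
    return Image2D(data=img, pixel_size=pix)  # type: ignore[arg-type]
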