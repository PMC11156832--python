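"""Rigid alignment of repeated acquisitions and ROI propagation.

The estimation contract is accuracy, not optimizer identity: a multiscale
6 degrees-of-freedom rigid registration maximizing mutual information
(32-bin Mattes implementation, coarse-to-fine x4/x2/x1 schedule) must
recover known transforms within a quarter voxel and half a degree on the
phantom. Estimation may interpolate internally (linear); only the final
label/value resampling is nearest-neighbour so that ROI labels are never
smoothed into new values.

ROI geometry default: vessel ROIs are spheres of diameter ~0.8x the local
vessel diameter placed on tube centerlines; each parenchymal partner is the
same voxel-index sphere translated sideways into background, which
guarantees the identical-voxel-count pairing the CNR estimator requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .rigid import RigidTransform, compose, invert, resample_linear, resample_nn
from .volume import Volume3D

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "compose",
    "invert",
    "resample_linear",
    "resample_nn",
    "RegistrationResult",
    "RoiLabel",
    "RoiSet",
    "RoiPropagationError",
    "estimate_rigid",
    "build_roi_set",
    "propagate_rois",
]


# ---------------------------------------------------------------------------
# mutual-information rigid estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of :func:`estimate_rigid`.

    ``transform`` maps the moving volume into the fixed space, i.e.
    ``resample_linear(moving, transform, fixed)`` overlays the fixed volume.
    Non-convergence is flagged, never silently returned as success.
    """

    transform: RigidTransform
    final_metric: float
    converged: bool
    stop_description: str
    n_levels: int


def _to_sitk(volume: Volume3D) -> sitk.Image:
    # our arrays are (x, y, z); SimpleITK expects (z, y, x) buffers
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(volume.data, dtype=np.float32).T))
    img.SetSpacing(tuple(float(v) for v in volume.voxel_size))
    img.SetOrigin(tuple(float(o) for o in volume.affine[:3, 3]))
    direction = volume.affine[:3, :3] / np.asarray(volume.voxel_size)[None, :]
    img.SetDirection(tuple(direction.flatten()))
    return img


def estimate_rigid(moving: Volume3D, fixed: Volume3D, n_levels: int = 3) -> RegistrationResult:
    """Estimate the rigid transform mapping ``moving`` into ``fixed`` space.

    Mattes mutual information (32 bins) on the full voxel grid, optimized by
    regular-step gradient descent with physical-shift parameter scaling,
    under a coarse-to-fine pyramid of ``n_levels`` (shrink factors
    ..., 4, 2, 1; matching smoothing sigmas ..., 2, 1, 0 voxels).
    """
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)

    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=300,
        gradientMagnitudeTolerance=1e-8,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2**k for k in range(n_levels - 1, -1, -1)]
    reg.SetShrinkFactorsPerLevel(shrinkFactors=shrink)
    reg.SetSmoothingSigmasPerLevel(smoothingSigmas=[max(s // 2, 0) for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(initial, inPlace=False)

    out = reg.Execute(f_img, m_img)
    stop = reg.GetOptimizerStopConditionDescription()
    converged = "Maximum number of iterations" not in stop
    if not converged:
        logger.warning("rigid registration did not converge: %s", stop)

    euler = sitk.Euler3DTransform(out if not isinstance(out, sitk.CompositeTransform) else out.GetNthTransform(0))
    # SimpleITK's transform maps fixed-space points to moving-space points;
    # our convention is the physical motion of the moving volume, i.e. its inverse.
    H = np.eye(4)
    H[:3, :3] = np.asarray(euler.GetMatrix()).reshape(3, 3)
    c = np.asarray(euler.GetCenter())
    H[:3, 3] = np.asarray(euler.GetTranslation()) + c - H[:3, :3] @ c
    fixed_to_moving = RigidTransform.from_matrix(H)
    return RegistrationResult(
        transform=invert(fixed_to_moving),
        final_metric=float(reg.GetMetricValue()),
        converged=converged,
        stop_description=stop,
        n_levels=n_levels,
    )


# ---------------------------------------------------------------------------
# ROI sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiLabel:
    name: str
    caliber_class: str
    kind: str  # "vessel" | "parenchyma"


@dataclass
class RoiSet:
    """Integer label volume plus label metadata and vessel->parenchyma pairing."""

    label_volume: Volume3D
    labels: dict[int, RoiLabel]
    pairing: dict[int, int]  # vessel label -> parenchyma label

    def voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.label_volume.data == label))

    def indices(self, label: int) -> tuple[np.ndarray, ...]:
        return np.nonzero(self.label_volume.data == label)

    def vessel_labels(self) -> list[int]:
        return sorted(k for k, v in self.labels.items() if v.kind == "vessel")

    def validate_pairing(self) -> None:
        """Paired ROIs must have identical voxel counts (CNR contract)."""
        for v_lab, p_lab in self.pairing.items():
            nv, np_ = self.voxel_count(v_lab), self.voxel_count(p_lab)
            if nv != np_:
                raise ValueError(
                    f"vessel ROI {v_lab} has {nv} voxels but its parenchymal "
                    f"partner {p_lab} has {np_}"
                )

    def to_sidecar(self) -> dict:
        return {
            "labels": {str(k): vars(v) for k, v in self.labels.items()},
            "pairing": {str(k): v for k, v in self.pairing.items()},
        }


class RoiPropagationError(RuntimeError):
    pass


def _sphere_offsets(radius_mm: float, voxel_size: np.ndarray) -> np.ndarray:
    """Integer index offsets of voxels whose centers fall inside a sphere."""
    half = np.maximum(np.ceil(radius_mm / voxel_size).astype(int), 0)
    rng = [np.arange(-h, h + 1) for h in half]
    ii, jj, kk = np.meshgrid(*rng, indexing="ij")
    offs = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    d = np.linalg.norm(offs * voxel_size, axis=1)
    keep = offs[d <= radius_mm]
    if len(keep) == 0:  # degenerate sphere: at least the center voxel
        keep = np.zeros((1, 3), dtype=int)
    return keep


def build_roi_set(
    tree,
    reference: Volume3D,
    n_rois: int = 17,
    seed: int = 0,
    min_segment_radius: float = 0.2,
    margin_mm: float = 0.3,
    min_sphere_radius_mm: float = 0.45,
) -> RoiSet:
    """Place ``n_rois`` vessel ROIs on tube centerlines with same-size
    parenchymal partners beside them.

    Vessel ROIs are spheres of radius 0.8x the local tube radius (at least
    one voxel) centered on segment midpoint samples, spread across caliber
    classes from largest to smallest. Each parenchymal partner is the same
    index-offset sphere translated perpendicular to the tube into a position
    whose whole extent clears every tube by ``margin_mm``.
    """
    rng = np.random.default_rng(seed)
    vs = np.asarray(reference.voxel_size, dtype=float)
    shape = np.asarray(reference.shape)
    segments = [s for s in tree.segments if s.radius >= min_segment_radius]
    segments.sort(key=lambda s: -s.radius)
    if not segments:
        raise ValueError("no tree segments meet the minimum radius for ROI placement")

    from .phantom import _point_segment_distance  # local import avoids a cycle

    def min_tube_clearance(point: np.ndarray) -> float:
        return min(
            float(_point_segment_distance(point, s)) - s.radius for s in tree.segments
        )

    label_data = np.zeros(reference.shape, dtype=np.int32)
    labels: dict[int, RoiLabel] = {}
    pairing: dict[int, int] = {}
    placed = 0
    fractions = [0.5, 0.3, 0.7]
    attempts = [(seg, f) for f in fractions for seg in segments]
    for seg, f in attempts:
        if placed >= n_rois:
            break
        center_w = np.asarray(seg.start) + f * (np.asarray(seg.end) - np.asarray(seg.start))
        # never smaller than min_sphere_radius_mm (default: above half the
        # diagonal of a 0.4 x 0.4 x 0.5 mm voxel), so every label keeps at
        # least one voxel under nearest-neighbour propagation to coarse grids
        sphere_r = max(0.8 * seg.radius, min_sphere_radius_mm, 0.6 * float(vs.max()))
        offs = _sphere_offsets(sphere_r, vs)
        center_idx = np.round(center_w / vs).astype(int)
        vox = center_idx[None, :] + offs
        if np.any(vox < 0) or np.any(vox >= shape[None, :]):
            continue
        if np.any(label_data[vox[:, 0], vox[:, 1], vox[:, 2]] != 0):
            continue
        # find a perpendicular integer offset placing the partner in background
        axis = np.asarray(seg.end) - np.asarray(seg.start)
        axis = axis / np.linalg.norm(axis)
        helper = np.array([1.0, 0, 0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1, 0])
        u = np.cross(axis, helper)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        partner_offset = None
        for ang in rng.permutation(np.arange(0, 360, 30)):
            direction = np.cos(np.deg2rad(ang)) * u + np.sin(np.deg2rad(ang)) * v
            # the partner must clear both the tube and the vessel sphere itself
            base_dist = max(seg.radius + sphere_r, 2.0 * sphere_r) + margin_mm
            for dist in (base_dist + np.arange(0.0, 2.1, 0.4)):
                cand_w = center_w + dist * direction
                cand_idx = np.round(cand_w / vs).astype(int)
                cvox = cand_idx[None, :] + offs
                if np.any(cvox < 0) or np.any(cvox >= shape[None, :]):
                    continue
                if min_tube_clearance(cand_idx * vs) < sphere_r + margin_mm:
                    continue
                if np.any(label_data[cvox[:, 0], cvox[:, 1], cvox[:, 2]] != 0):
                    continue
                # index rounding can pull the spheres closer than their
                # continuous separation: verify disjointness exactly
                flat_v = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), tuple(shape))
                flat_p = np.ravel_multi_index((cvox[:, 0], cvox[:, 1], cvox[:, 2]), tuple(shape))
                if np.intersect1d(flat_v, flat_p).size:
                    continue
                partner_offset = cand_idx - center_idx
                break
            if partner_offset is not None:
                break
        if partner_offset is None:
            continue
        v_lab = placed + 1
        p_lab = 100 + placed + 1
        label_data[vox[:, 0], vox[:, 1], vox[:, 2]] = v_lab
        pvox = vox + partner_offset[None, :]
        label_data[pvox[:, 0], pvox[:, 1], pvox[:, 2]] = p_lab
        labels[v_lab] = RoiLabel(name=f"vessel_{v_lab:02d}", caliber_class=seg.caliber_class, kind="vessel")
        labels[p_lab] = RoiLabel(name=f"parenchyma_{v_lab:02d}", caliber_class=seg.caliber_class, kind="parenchyma")
        pairing[v_lab] = p_lab
        placed += 1
    if placed < n_rois:
        raise RuntimeError(f"could only place {placed} of {n_rois} requested ROIs")
    rois = RoiSet(
        label_volume=Volume3D(label_data, reference.voxel_size, reference.affine.copy()),
        labels=labels,
        pairing=pairing,
    )
    rois.validate_pairing()
    return rois


def propagate_rois(rois: RoiSet, transform: RigidTransform, reference: Volume3D) -> RoiSet:
    """Move an ROI set into another space by nearest-neighbour label
    resampling; pairing metadata is preserved.

    Voxel counts change under resolution change (quantization); counts per
    label are logged, and a label that vanishes entirely raises
    :class:`RoiPropagationError` naming it.
    """
    moved = resample_nn(rois.label_volume, transform, reference)
    moved = moved.copy_with(np.asarray(moved.data).astype(rois.label_volume.data.dtype))
    out = RoiSet(label_volume=moved, labels=dict(rois.labels), pairing=dict(rois.pairing))
    for lab, meta in rois.labels.items():
        n = out.voxel_count(lab)
        logger.info("label %d (%s): %d voxels after propagation", lab, meta.name, n)
        if n == 0:
            raise RoiPropagationError(
                f"label {lab} ({meta.name}) vanished entirely after propagation"
            )
    return out
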