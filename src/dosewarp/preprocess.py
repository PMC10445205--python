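"""Preprocessing chain: intensity normalization, resampling, field-of-view
cropping and bone-based rigid alignment.

The chain mirrors standard CBCT-guided-radiotherapy practice: daily CBCTs are
first rigidly aligned to the planning CT on bony anatomy (patient positioning),
both volumes are cropped to the common field of view, resampled to a fixed
grid, and intensities are clipped to [-1024, 1575] HU and scaled to [0, 1]
before any intensity-based registration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from ._sitk import from_sitk, rigid_from_sitk, rigid_to_sitk, to_sitk
from .grids import GridError, ImageVolume, LabelVolume, RigidTransform

__all__ = [
    "GridSpec",
    "clip_normalize",
    "resample_to_grid",
    "crop_to_fov",
    "rigid_register_bone",
    "apply_rigid",
]

#: Default HU clipping window.
HU_LO, HU_HI = -1024.0, 1575.0

#: Default bone threshold (HU): above typical soft tissue, below dense cortical.
BONE_HU = 200.0


@dataclass(frozen=True)
class GridSpec:
    """Fully specified target grid (shape, spacing in mm, origin in mm)."""

    shape: tuple
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    @classmethod
    def of(cls, vol: ImageVolume) -> "GridSpec":
        return cls(tuple(vol.shape), tuple(vol.spacing), tuple(vol.origin))


def clip_normalize(img: ImageVolume, lo: float = HU_LO, hi: float = HU_HI) -> ImageVolume:
    """Clip intensities to [lo, hi] and rescale linearly to [0, 1]."""
    if lo >= hi:
        raise ValueError(f"lo must be < hi, got lo={lo}, hi={hi}")
    out = (np.clip(img.data, lo, hi) - lo) / (hi - lo)
    return img.with_data(out)


_SITK_INTERP = {
    "bspline": sitk.sitkBSpline,
    "trilinear": sitk.sitkLinear,
    "nearest": sitk.sitkNearestNeighbor,
}


def resample_to_grid(
    vol: ImageVolume | LabelVolume,
    target: GridSpec,
    method: str = "bspline",
    transform: RigidTransform | None = None,
):
    """Resample onto ``target``; labels allow nearest-neighbour only.

    ``transform`` (optional) maps target-frame points into the source frame
    (resampling convention) and lets rigid alignment and regridding happen in
    one interpolation pass.
    """
    if method not in _SITK_INTERP:
        raise ValueError(f"method must be one of {sorted(_SITK_INTERP)}")
    is_label = isinstance(vol, LabelVolume)
    if is_label and method != "nearest":
        raise ValueError("label volumes must be resampled with method='nearest'")
    img = to_sitk(vol, dtype=np.float32 if not is_label else np.int16)
    tr = rigid_to_sitk(transform) if transform is not None else sitk.Transform()
    default = float(vol.data.min())
    out = sitk.Resample(
        img,
        [int(n) for n in target.shape],
        tr,
        _SITK_INTERP[method],
        [float(o) for o in target.origin],
        [float(s) for s in target.spacing],
        (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        default,
    )
    res = from_sitk(out, like=vol)
    if is_label:
        return dataclasses.replace(
            vol,
            data=np.round(res.data).astype(np.int16),
            spacing=res.spacing,
            origin=res.origin,
        )
    return dataclasses.replace(vol, data=res.data, spacing=res.spacing, origin=res.origin)


def apply_rigid(
    moving: ImageVolume | LabelVolume,
    transform: RigidTransform,
    target: GridSpec | None = None,
    method: str | None = None,
):
    """Resample ``moving`` through a rigid transform onto ``target`` (default:
    the moving volume's own grid)."""
    target = target or GridSpec.of(moving)
    if method is None:
        method = "nearest" if isinstance(moving, LabelVolume) else "trilinear"
    return resample_to_grid(moving, target, method=method, transform=transform)


def _fov_box(vol: ImageVolume) -> tuple:
    lo = vol.origin
    hi = vol.origin + (np.array(vol.shape) - 1) * vol.spacing
    return lo, hi


def crop_to_fov(*volumes: ImageVolume):
    """Crop all volumes to the intersection of their fields of view.

    All inputs must already live on a common grid (same spacing/origin lattice,
    typically after rigid alignment); each output covers the voxels whose world
    positions fall inside every input's bounding box.
    """
    if len(volumes) < 2:
        raise ValueError("need at least two volumes")
    ref = volumes[0]
    los, his = zip(*[_fov_box(v) for v in volumes])
    lo = np.max(los, axis=0)
    hi = np.min(his, axis=0)
    if np.any(hi < lo):
        raise GridError("fields of view do not intersect")
    out = []
    for v in volumes:
        i0 = np.ceil((lo - v.origin) / v.spacing - 1e-9).astype(int)
        i1 = np.floor((hi - v.origin) / v.spacing + 1e-9).astype(int)
        sl = tuple(slice(a, b + 1) for a, b in zip(i0, i1))
        out.append(
            dataclasses.replace(
                v, data=v.data[sl], origin=v.origin + i0 * v.spacing
            )
        )
    return tuple(out)


def rigid_register_bone(
    fixed: ImageVolume,
    moving: ImageVolume,
    bone_hu: float = BONE_HU,
    smooth_mm: float = 4.0,
    seed: int = 0,
) -> RigidTransform:
    """Bone-based 6-DOF rigid registration.

    Both volumes are thresholded at ``bone_hu`` to isolate bony anatomy, the
    binary masks are Gaussian-smoothed into soft indicators, and a rigid
    Euler transform (fixed→moving, resampling convention) is found by
    mean-squares alignment of the indicators with a multi-resolution gradient
    descent.  Deterministic for fixed inputs and seed.
    """
    f_mask = (fixed.data > bone_hu).astype(np.float32)
    m_mask = (moving.data > bone_hu).astype(np.float32)
    if f_mask.sum() == 0 or m_mask.sum() == 0:
        raise ValueError(f"no voxels above bone threshold {bone_hu} HU")
    f_img = sitk.SmoothingRecursiveGaussian(
        to_sitk(fixed.with_data(f_mask)), smooth_mm
    )
    m_img = sitk.SmoothingRecursiveGaussian(
        to_sitk(moving.with_data(m_mask)), smooth_mm
    )
    init = sitk.Euler3DTransform(
        sitk.CenteredTransformInitializer(
            f_img, m_img, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.MOMENTS,
        )
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-4, numberOfIterations=200,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(init, inPlace=True)
    reg.Execute(f_img, m_img)
    return rigid_from_sitk(init)
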