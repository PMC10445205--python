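"""Conversions between package volumes and SimpleITK images.

SimpleITK array views are indexed (z, y, x); the package uses (x, y, z).
All conversions transpose accordingly and carry spacing/origin through.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk

from .grids import ImageVolume, RigidTransform


def to_sitk(vol: ImageVolume, dtype=np.float32) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T.astype(dtype)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def from_sitk(img: sitk.Image, like: ImageVolume | None = None, frame_id: str = "planning") -> ImageVolume:
    data = sitk.GetArrayFromImage(img).T
    return ImageVolume(
        data=data.astype(np.float64),
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        frame_id=like.frame_id if like is not None else frame_id,
    )


def rigid_to_sitk(t: RigidTransform) -> sitk.Euler3DTransform:
    tr = sitk.Euler3DTransform()
    tr.SetCenter(tuple(float(c) for c in t.center))
    tr.SetMatrix(tuple(float(v) for v in t.matrix.ravel()))
    tr.SetTranslation(tuple(float(v) for v in t.translation))
    return tr


def rigid_from_sitk(tr) -> RigidTransform:
    R = np.array(tr.GetMatrix()).reshape(3, 3)
    return RigidTransform.from_matrix(
        R, translation=np.array(tr.GetTranslation()), center=np.array(tr.GetCenter())
    )
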