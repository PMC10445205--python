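"""Grid-aware volume containers and NIfTI-1 I/O.

Conventions used throughout the package:

* voxel indices are 0-based, axis order ``(x, y, z)``;
* world coordinates (mm) of voxel ``(i, j, k)`` are ``origin + index * spacing``
  (axis-aligned grids only — oblique acquisitions are out of scope);
* two volumes are *co-registered* iff they share shape, spacing, origin and
  ``frame_id``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "RigidTransform",
    "LABEL_MAP",
    "read_volume",
    "write_volume",
]

#: Fixed label encoding for the pelvic structure set.
LABEL_MAP: Mapping[int, str] = {
    0: "background",
    1: "body",
    2: "rectum",
    3: "bladder",
    4: "prostate",
}

#: Structures evaluated geometrically / dosimetrically (excludes background/body).
ORGAN_LABELS: Mapping[str, int] = {"rectum": 2, "bladder": 3, "prostate": 4}


class GridError(ValueError):
    """Raised on geometry/grid mismatches."""


def _as_triple(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(-1)
    if a.size == 1:
        a = np.repeat(a, 3)
    if a.size != 3:
        raise ValueError(f"expected 3 components, got {a.size}")
    return a


@dataclass
class ImageVolume:
    """Scalar 3D grid (HU, Gy, or unitless) with spacing/origin metadata."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame_id: str = "planning"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={self.data.ndim}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    # -- grid helpers ------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    def same_grid(self, other: "ImageVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def co_registered(self, other: "ImageVolume") -> bool:
        return self.same_grid(other) and self.frame_id == other.frame_id

    def world_coords(self) -> tuple:
        """Per-axis world coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def with_data(self, data: np.ndarray, frame_id: str | None = None) -> "ImageVolume":
        return dataclasses.replace(
            self, data=np.asarray(data), frame_id=frame_id or self.frame_id
        )

    def copy(self) -> "ImageVolume":
        return dataclasses.replace(self, data=self.data.copy())


@dataclass
class LabelVolume(ImageVolume):
    """Integer 3D grid encoding the pelvic structure set (codes 0-4)."""

    label_map: Mapping[int, str] = field(default_factory=lambda: dict(LABEL_MAP))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label data must be integer-valued")
            self.data = np.round(self.data).astype(np.int16)
        bad = np.setdiff1d(np.unique(self.data), list(self.label_map))
        if bad.size:
            raise ValueError(f"labels outside {sorted(self.label_map)}: {bad.tolist()}")

    def mask(self, label: int | str) -> np.ndarray:
        if isinstance(label, str):
            inv = {v: k for k, v in self.label_map.items()}
            label = inv[label]
        return self.data == label


@dataclass
class RigidTransform:
    """6-DOF rigid transform: ZYX Euler rotation about ``center`` plus translation.

    Maps points of the *fixed* frame into the *moving* frame (resampling /
    pull-back convention): ``y = R @ (x - center) + center + translation``.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = _as_triple(self.rotation)
        self.translation = _as_triple(self.translation)
        self.center = _as_triple(self.center)

    @property
    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of world points (mm)."""
        p = np.asarray(points, dtype=float)
        return (p - self.center) @ self.matrix.T + self.center + self.translation

    @staticmethod
    def _euler_zyx(R: np.ndarray) -> tuple:
        """ZYX Euler angles of a rotation matrix."""
        ry = np.arcsin(-np.clip(R[2, 0], -1.0, 1.0))
        if abs(np.cos(ry)) > 1e-12:
            rx = np.arctan2(R[2, 1], R[2, 2])
            rz = np.arctan2(R[1, 0], R[0, 0])
        else:  # gimbal lock
            rx = np.arctan2(-R[1, 2], R[1, 1])
            rz = 0.0
        return rx, ry, rz

    @classmethod
    def from_matrix(cls, R: np.ndarray, translation, center=(0, 0, 0)) -> "RigidTransform":
        return cls(rotation=cls._euler_zyx(np.asarray(R)), translation=translation, center=center)

    def inverse(self) -> "RigidTransform":
        """Exact inverse, returned in matrix-equivalent Euler form."""
        inv = RigidTransform.from_matrix(self.matrix.T, np.zeros(3), self.center)
        # solve translation so inv(self(x)) == x
        y = self.apply(self.center)
        inv.translation = self.center - inv.apply(y)
        return inv

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.allclose(self.rotation, 0, atol=tol)
            and np.allclose(self.translation, 0, atol=tol)
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume (or a 4D displacement stack) as NIfTI-1."""
    path = Path(path)
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(np.asarray(data), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(tuple(vol.spacing) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, kind: str = "scalar") -> ImageVolume | LabelVolume:
    """Read a NIfTI-1 volume.

    Parameters
    ----------
    path : NIfTI-1 file (.nii / .nii.gz).
    kind : ``"scalar"`` for images/doses, ``"label"`` for structure sets
        (validates the 0-4 code set).
    """
    if kind not in ("scalar", "label"):
        raise ValueError(f"kind must be 'scalar' or 'label', got {kind!r}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        aff = img.affine
    except Exception as exc:  # malformed header / not a NIfTI
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3].copy()
    if kind == "label":
        return LabelVolume(data=data, spacing=spacing, origin=origin)
    return ImageVolume(data=data.astype(np.float64), spacing=spacing, origin=origin)
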