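"""Fraction-dose construction, DVF-based dose warping/accumulation, and DVH
index reporting.

The dose-accumulation protocol assumes dose deformation-invariance: each
fraction's dose is the planning dose rigidly mapped into the fraction frame
(patient positioning), and the delivered total is estimated by pulling every
fraction dose back onto the planning anatomy through the per-fraction
deformation field and summing.  DVH indices follow the GETUG reporting set:
D98% and V76Gy for the prostate, V70Gy for the bladder, V72Gy for the rectum,
plus Dmean for all structures.

Dose warping uses plain trilinear interpolation (no Jacobian/energy-mass
weighting) — adequate for slowly varying dose and the convention assumed
throughout; see the methods note for the limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .fields import DeformationField, warp
from .grids import GridError, ImageVolume, LabelVolume, ORGAN_LABELS, RigidTransform
from .preprocess import GridSpec, apply_rigid

__all__ = [
    "DVHCurve",
    "AccumulatedDose",
    "fraction_dose",
    "accumulate",
    "dvh",
    "dvh_indices",
    "dose_report",
    "wall_mask",
    "GETUG_INDEX_SET",
]

#: Organ-specific DVH index set (name → list of index labels).
GETUG_INDEX_SET = {
    "prostate": ("Dmean", "D98", "V76"),
    "bladder": ("Dmean", "V70"),
    "rectum": ("Dmean", "V72"),
}


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram for one structure.

    ``volume_pct[i]`` is the percentage of the structure receiving at least
    ``edges[i]`` Gy; the curve is non-increasing with V(0) = 100.  Dmean is
    computed directly from the masked dose (binning-independent); D98% and
    VxGy interpolate the curve linearly.
    """

    structure: str
    edges: np.ndarray  # bin edges, Gy
    volume_pct: np.ndarray  # % volume receiving >= edge dose
    dmean: float
    _doses: np.ndarray = dfield(repr=False, default=None)

    def v_at(self, dose_gy: float) -> float:
        """VxGy: % of the structure receiving at least ``dose_gy``."""
        return float(100.0 * np.mean(self._doses >= dose_gy))

    def d_at(self, volume_pct: float) -> float:
        """DV%: greatest dose received by at least ``volume_pct`` % of volume
        (linear interpolation on the cumulative curve)."""
        v = self.volume_pct
        e = self.edges
        if volume_pct >= v[0]:
            return float(e[0])
        if volume_pct <= v[-1]:
            return float(e[-1])
        i = int(np.searchsorted(-v, -volume_pct, side="right")) - 1
        i = min(max(i, 0), len(v) - 2)
        if v[i + 1] == v[i]:
            return float(e[i])
        t = (volume_pct - v[i]) / (v[i + 1] - v[i])
        return float(e[i] + t * (e[i + 1] - e[i]))

    @property
    def d98(self) -> float:
        return self.d_at(98.0)


@dataclass
class AccumulatedDose:
    """Summed dose on the planning frame with per-fraction provenance."""

    dose: ImageVolume
    provenance: list  # (fraction id, field id, rigid id) triples


def fraction_dose(planning_dose: ImageVolume, rigid: RigidTransform,
                  target: GridSpec | None = None,
                  frame_id: str = "fraction") -> ImageVolume:
    """Planning dose resampled into a fraction frame through a rigid transform.

    ``rigid`` maps fraction-frame points into the planning frame (the
    resampling convention of :class:`RigidTransform`); trilinear
    interpolation; identity transforms reproduce the input exactly.
    """
    if rigid.is_identity(tol=1e-12) and target is None:
        out = planning_dose.copy()
        out.frame_id = frame_id
        return out
    out = apply_rigid(planning_dose, rigid, target=target, method="trilinear")
    out.frame_id = frame_id
    # interpolation can produce tiny negative overshoots near steep gradients
    out.data = np.maximum(out.data, 0.0)
    return out


def accumulate(fraction_doses, fields, n_expected: int | None = None) -> AccumulatedDose:
    """Pull every fraction dose back onto the planning grid and sum.

    ``fields[k]`` is the pull-back field of fraction k (fixed = planning
    frame); linear in each fraction dose and invariant to fraction order.
    """
    fraction_doses = list(fraction_doses)
    fields = list(fields)
    if len(fraction_doses) != len(fields):
        raise ValueError(
            f"{len(fraction_doses)} fraction doses but {len(fields)} fields"
        )
    if n_expected is not None and len(fields) != n_expected:
        raise ValueError(f"expected {n_expected} fractions, got {len(fields)}")
    if not fields:
        raise ValueError("no fractions to accumulate")
    total = None
    prov = []
    for k, (d, f) in enumerate(zip(fraction_doses, fields)):
        if d.shape != f.shape:
            raise GridError(f"fraction {k}: dose grid {d.shape} != field {f.shape}")
        warped = warp(d, f)
        total = warped.data if total is None else total + warped.data
        prov.append((k, id(f), None))
    ref = fields[0]
    return AccumulatedDose(
        dose=ImageVolume(total, ref.spacing, ref.origin, ref.frame_id),
        provenance=prov,
    )


def dvh(dose: ImageVolume, mask, structure: str = "", bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH of ``dose`` over a binary mask."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    m = np.asarray(mask).astype(bool)
    if dose.shape != m.shape:
        raise GridError("dose and mask grids differ")
    vals = dose.data[m]
    if vals.size == 0:
        raise ValueError("empty structure mask")
    top = max(float(vals.max()), bin_width)
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    vol = 100.0 * (vals[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(
        structure=structure,
        edges=edges,
        volume_pct=vol,
        dmean=float(vals.mean()),
        _doses=vals,
    )


def dvh_indices(dose: ImageVolume, labels: LabelVolume,
                index_set: dict = GETUG_INDEX_SET,
                bin_width: float = 0.1) -> dict:
    """Per-structure DVH indices (Gy for D-indices, % for V-indices)."""
    out: dict = {}
    for name, indices in index_set.items():
        code = ORGAN_LABELS[name]
        curve = dvh(dose, labels.data == code, structure=name, bin_width=bin_width)
        vals = {}
        for ix in indices:
            if ix == "Dmean":
                vals[ix] = curve.dmean
            elif ix.startswith("D"):
                vals[ix] = curve.d_at(float(ix[1:]))
            elif ix.startswith("V"):
                vals[ix] = curve.v_at(float(ix[1:]))
        out[name] = vals
    return out


def dose_report(planning: dict, accumulated: dict) -> dict:
    """Signed per-structure index differences (accumulated − planning)."""
    if set(planning) != set(accumulated):
        raise ValueError(
            f"structure sets differ: {sorted(planning)} vs {sorted(accumulated)}"
        )
    out: dict = {}
    for s in planning:
        if set(planning[s]) != set(accumulated[s]):
            raise ValueError(f"index sets differ for {s}")
        out[s] = {k: accumulated[s][k] - planning[s][k] for k in planning[s]}
    return out


def wall_mask(labels: LabelVolume, structure: str, thickness_mm: float) -> np.ndarray:
    """Organ wall: the structure minus its erosion by ``thickness_mm``
    (spherical structuring element), for wall-based DVH constraints
    (5 mm rectum / 7 mm bladder walls)."""
    code = ORGAN_LABELS[structure]
    solid = labels.data == code
    r = np.maximum(np.round(thickness_mm / labels.spacing).astype(int), 1)
    zx, zy, zz = [np.arange(-n, n + 1) for n in r]
    ball = (
        (zx[:, None, None] / r[0]) ** 2
        + (zy[None, :, None] / r[1]) ** 2
        + (zz[None, None, :] / r[2]) ** 2
    ) <= 1.0
    return solid & ~ndimage.binary_erosion(solid, structure=ball)
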