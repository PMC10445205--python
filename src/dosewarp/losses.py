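"""Registration losses: soft-binned NMI, one-hot label L1, diffusion smoothness.

Each loss has a public form operating on package volume types and an internal
``*_grad`` form operating on raw arrays that also returns the analytic
gradient, used by the hand-rolled training loop.

Definitions
-----------
* ``nmi_loss`` is the negated Studholme normalized mutual information
  ``-(H(a) + H(b)) / H(a, b)`` estimated from a Parzen joint histogram with
  triangular (linear interpolation) kernels; lower = more similar, bounded
  below by -2 (the hard-binned self-similarity value; soft binning keeps
  self-NMI slightly above it).  Images constant to the binning (zero
  marginal entropy) have no intensity information to share: the loss falls
  back to -1.0 (the independence value) with zero gradient — never NaN.
* ``mask_l1_loss`` one-hot encodes the four non-background structures
  (body, rectum, bladder, prostate), sums absolute differences over channels
  and averages over voxels.  Two disjoint single-structure masks each
  covering a volume fraction f therefore give exactly 2f.
* ``smoothness_loss`` is the diffusion regularizer: the mean squared
  forward-difference gradient, averaged over the three displacement
  components, three spatial axes and all difference positions.  A linear
  field u_c = c·x_a (one component, one axis) gives exactly c²/9.
"""

from __future__ import annotations

import numpy as np

from .fields import DeformationField
from .grids import ImageVolume, LabelVolume

__all__ = ["nmi_loss", "mask_l1_loss", "smoothness_loss", "total_loss"]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# NMI
# ---------------------------------------------------------------------------

def _hat_weights(v: np.ndarray, bins: int):
    """Triangular-kernel bin assignments for values in [0, 1].

    Returns (i0, w0, w1): each value contributes w0 to bin i0 and w1 = 1 - w0
    to bin i0 + 1 (bin centers at k / (bins - 1)).
    """
    t = np.clip(v, 0.0, 1.0) * (bins - 1)
    i0 = np.minimum(np.floor(t).astype(np.intp), bins - 2)
    f = t - i0
    return i0, 1.0 - f, f


def _joint_hist(a, b, bins):
    ia, wa0, wa1 = _hat_weights(a, bins)
    ib, wb0, wb1 = _hat_weights(b, bins)
    p = np.zeros((bins, bins))
    flat = p.ravel()
    for da, wa in ((0, wa0), (1, wa1)):
        for db, wb in ((0, wb0), (1, wb1)):
            np.add.at(flat, (ia + da) * bins + (ib + db), wa * wb)
    p /= a.size
    return p, (ia, wa0, wa1), (ib, wb0, wb1)


def _entropy(p):
    q = p[p > _EPS]
    return float(-(q * np.log(q)).sum())


def nmi_loss_grad(a: np.ndarray, b: np.ndarray, bins: int = 32):
    """Negated NMI and its gradient with respect to ``b`` (per voxel)."""
    a = np.asarray(a, dtype=np.float64).ravel()
    bf = np.asarray(b, dtype=np.float64).ravel()
    n = a.size
    p, (ia, wa0, wa1), (ib, wb0, wb1) = _joint_hist(a, bf, bins)
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    ha, hb, hab = _entropy(pa), _entropy(pb), _entropy(p)
    if ha < 1e-9 or hb < 1e-9 or hab < 1e-9:
        return -1.0, np.zeros_like(np.asarray(b, dtype=np.float64))
    nmi = (ha + hb) / hab
    # dL/dp_ij for L = -(Ha+Hb)/Hab
    dha = -(1.0 + np.log(np.maximum(pa, _EPS)))  # dHa/dpa_i
    dhb = -(1.0 + np.log(np.maximum(pb, _EPS)))
    dhab = -(1.0 + np.log(np.maximum(p, _EPS)))
    dL_dp = -(dha[:, None] + dhb[None, :]) / hab + nmi / hab * dhab
    # chain into voxels of b through the triangular kernel (dw/db = ±(bins-1))
    k = (bins - 1) / n
    g = np.zeros(n)
    for da, wa in ((0, wa0), (1, wa1)):
        rows = ia + da
        g += wa * k * (dL_dp[rows, ib + 1] - dL_dp[rows, ib])
    return float(-nmi), g.reshape(np.asarray(b).shape)


def nmi_loss(a: ImageVolume | np.ndarray, b: ImageVolume | np.ndarray,
             bins: int = 32) -> float:
    """Negated soft-binned NMI between two [0, 1]-normalized volumes."""
    if bins < 8:
        raise ValueError("bins must be >= 8")
    da = a.data if isinstance(a, ImageVolume) else np.asarray(a)
    db = b.data if isinstance(b, ImageVolume) else np.asarray(b)
    return nmi_loss_grad(da, db, bins)[0]


# ---------------------------------------------------------------------------
# one-hot label L1
# ---------------------------------------------------------------------------

FOREGROUND_LABELS = (1, 2, 3, 4)


def one_hot(labels: np.ndarray, codes=FOREGROUND_LABELS) -> np.ndarray:
    """(C, X, Y, Z) float32 indicators for the non-background codes."""
    lab = np.asarray(labels)
    return np.stack([(lab == c) for c in codes]).astype(np.float32)


def l1_grad(fixed_oh: np.ndarray, warped_oh: np.ndarray):
    """Mean-over-voxel, summed-over-channel absolute difference + gradient
    with respect to ``warped_oh``."""
    n = float(np.prod(fixed_oh.shape[1:]))
    diff = warped_oh.astype(np.float64) - fixed_oh
    loss = float(np.abs(diff).sum() / n)
    return loss, np.sign(diff) / n


def mask_l1_loss(fixed_labels: LabelVolume | np.ndarray,
                 warped_labels: LabelVolume | np.ndarray) -> float:
    """One-hot L1 between two label volumes (0 iff identical)."""
    fl = fixed_labels.data if isinstance(fixed_labels, LabelVolume) else np.asarray(fixed_labels)
    wl = warped_labels.data if isinstance(warped_labels, LabelVolume) else np.asarray(warped_labels)
    fc = set(np.unique(fl)) | set(np.unique(wl))
    if not fc <= set((0,) + FOREGROUND_LABELS):
        raise ValueError(f"unexpected label codes {sorted(fc)}")
    return l1_grad(one_hot(fl), one_hot(wl))[0]


# ---------------------------------------------------------------------------
# smoothness (diffusion regularizer)
# ---------------------------------------------------------------------------

def smoothness_grad(u: np.ndarray):
    """Diffusion loss and gradient for a (3, X, Y, Z) displacement array."""
    u = np.asarray(u, dtype=np.float64)
    loss = 0.0
    g = np.zeros_like(u)
    for ax in range(1, 4):
        d = np.diff(u, axis=ax)
        m = d.size
        loss += (d**2).sum() / m / 3.0
        gd = 2.0 * d / m / 3.0
        sl_hi = [slice(None)] * 4
        sl_lo = [slice(None)] * 4
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        g[tuple(sl_hi)] += gd
        g[tuple(sl_lo)] -= gd
    return float(loss), g


def smoothness_loss(field: DeformationField | np.ndarray) -> float:
    """Mean squared forward-difference gradient of the displacement.

    Averaged over components, axes and difference positions; zero for any
    constant field; a linear field u_c = c·x_a yields exactly c²/9.
    """
    if isinstance(field, DeformationField):
        u = np.moveaxis(field.displacement, -1, 0)
    else:
        u = np.asarray(field)
    return smoothness_grad(u)[0]


# ---------------------------------------------------------------------------
# variant-weighted totals
# ---------------------------------------------------------------------------

#: Loss weights per network variant (similarity, label, smoothness).
VARIANT_WEIGHTS = {
    "sc": {"nmi": 1.0, "smooth": 4.0},
    "msk": {"l1": 2.0, "smooth": 4.0},
    "sc_msk": {"nmi": 1.0, "l1": 2.0, "smooth": 4.0},
}


def total_loss(
    variant: str,
    field: DeformationField,
    fixed: ImageVolume | None = None,
    warped_moving: ImageVolume | None = None,
    fixed_labels: LabelVolume | None = None,
    warped_labels: LabelVolume | None = None,
    weights: dict | None = None,
    bins: int = 32,
):
    """Weighted total loss for a variant, with components reported separately.

    ``warped_moving`` / ``warped_labels`` are the moving image/labels already
    resampled through ``field``.
    """
    if variant not in VARIANT_WEIGHTS:
        raise ValueError(f"unknown variant {variant!r}")
    w = dict(VARIANT_WEIGHTS[variant])
    if weights:
        w.update(weights)
    comps: dict = {}
    if "nmi" in w:
        if fixed is None or warped_moving is None:
            raise ValueError(f"variant {variant!r} requires images")
        comps["nmi"] = nmi_loss(fixed, warped_moving, bins=bins)
    if "l1" in w:
        if fixed_labels is None or warped_labels is None:
            raise ValueError(f"variant {variant!r} requires label volumes")
        comps["l1"] = mask_l1_loss(fixed_labels, warped_labels)
    comps["smooth"] = smoothness_loss(field)
    total = sum(w[k] * comps[k] for k in comps)
    return total, comps
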