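"""Classical B-spline free-form deformation registration (non-DL comparator).

An NMI-driven FFD: displacements are parameterized by a cubic B-spline
control lattice (8 mm final spacing), optimized with an adaptive-step (Adam)
stochastic gradient descent on random voxel subsamples of the soft-binned NMI
similarity, over a 4-level multi-resolution image pyramid (resolution divided
by 4, 4, 2, 1 with Gaussian smoothing).  The whole chain — B-spline
evaluation, trilinear warping, NMI and its gradient — is the package's own
differentiable machinery, so the optimizer is fully deterministic under a
seed and runs in CPU seconds at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .fields import DeformationField, trilinear_sample_multi
from .grids import GridError, ImageVolume
from .losses import nmi_loss, nmi_loss_grad

__all__ = ["FFDConfig", "ffd_register", "bspline_to_dense", "cubic_bspline",
           "BSplineLattice"]


@dataclass
class FFDConfig:
    """Multi-resolution FFD configuration.

    ``samples_per_iteration`` random voxels feed each stochastic NMI gradient
    estimate; ``step_mm`` is the Adam step size in mm of control-point motion.
    """

    grid_spacing_mm: float = 8.0
    shrink_factors: tuple = (4, 4, 2, 1)
    smoothing_sigmas: tuple | None = None  # voxels; default factor/2
    iterations_per_level: int = 200
    samples_per_iteration: int = 2000
    step_mm: float = 0.4
    reg_weight: float = 0.1  # diffusion penalty on the control lattice
    nmi_bins: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.shrink_factors
        if any(a <= 0 for a in f) or any(
            f[i] < f[i + 1] for i in range(len(f) - 1)
        ):
            raise ValueError("shrink factors must be positive and non-increasing")
        if f[-1] != 1:
            raise ValueError("final shrink factor must be 1")
        if self.smoothing_sigmas is None:
            self.smoothing_sigmas = tuple(x / 2.0 for x in f)


# ---------------------------------------------------------------------------
# cubic B-spline lattice
# ---------------------------------------------------------------------------

def cubic_bspline(t: np.ndarray) -> np.ndarray:
    """The cubic B-spline kernel B3 on support |t| < 2 (partition of unity)."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    m1 = t < 1
    m2 = (t >= 1) & (t < 2)
    out[m1] = (4.0 - 6.0 * t[m1] ** 2 + 3.0 * t[m1] ** 3) / 6.0
    out[m2] = (2.0 - t[m2]) ** 3 / 6.0
    return out


@dataclass
class BSplineLattice:
    """Control-point lattice of displacements (mm) for an FFD.

    ``control`` has shape (nx, ny, nz, 3); control point (i, j, k) sits at
    world position ``origin + (i, j, k) * spacing``.
    """

    control: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = dfield(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @classmethod
    def covering(cls, shape, spacing, origin=(0.0, 0.0, 0.0),
                 cp_spacing: float = 8.0) -> "BSplineLattice":
        """Zero lattice covering a grid with the cubic-support margin."""
        extent = (np.asarray(shape) - 1) * np.asarray(spacing)
        ncp = np.ceil(extent / cp_spacing).astype(int) + 5
        lat_origin = np.asarray(origin, dtype=float) - 2.0 * cp_spacing
        return cls(np.zeros(tuple(ncp) + (3,)), (cp_spacing,) * 3, lat_origin)


def _lattice_coords(lattice: BSplineLattice, pts_mm: np.ndarray):
    """Per-point base index and 4-tap weights per axis; validates coverage."""
    ncp = np.array(lattice.control.shape[:3])
    t = (pts_mm - lattice.origin) / lattice.spacing
    if t.min() < 1.0 - 1e-9 or np.any(t.max(axis=0) > ncp - 2.0 + 1e-9):
        raise GridError(
            "lattice does not cover the requested points with cubic support"
        )
    base = np.floor(t).astype(np.intp)
    frac = t - base
    offs = np.arange(-1, 3)
    w = cubic_bspline(frac[..., None] - offs)  # (..., 3, 4)
    return base, w


def _eval_at_points(lattice: BSplineLattice, pts_mm: np.ndarray):
    """Displacement (mm) at arbitrary points + cached (base, weights)."""
    base, w = _lattice_coords(lattice, pts_mm)
    u = np.zeros(pts_mm.shape, dtype=np.float64)
    ctrl = lattice.control
    for dx in range(4):
        for dy in range(4):
            wxy = w[:, 0, dx] * w[:, 1, dy]
            ix = base[:, 0] + dx - 1
            iy = base[:, 1] + dy - 1
            for dz in range(4):
                u += (wxy * w[:, 2, dz])[:, None] * ctrl[
                    ix, iy, base[:, 2] + dz - 1
                ]
    return u, (base, w)


def _scatter_gradient(lattice: BSplineLattice, cache, g_pts: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_eval_at_points`: accumulate point gradients onto the
    control lattice."""
    base, w = cache
    g_ctrl = np.zeros_like(lattice.control)
    ncp = lattice.control.shape[:3]
    for dx in range(4):
        for dy in range(4):
            wxy = w[:, 0, dx] * w[:, 1, dy]
            ix = base[:, 0] + dx - 1
            iy = base[:, 1] + dy - 1
            for dz in range(4):
                flat = (ix * ncp[1] + iy) * ncp[2] + base[:, 2] + dz - 1
                np.add.at(
                    g_ctrl.reshape(-1, 3), flat,
                    (wxy * w[:, 2, dz])[:, None] * g_pts,
                )
    return g_ctrl


def bspline_to_dense(lattice: BSplineLattice, target) -> DeformationField:
    """Evaluate a control lattice as a dense field on ``target`` (a GridSpec
    or any object with shape/spacing/origin).

    Separable tensor-product cubic interpolation; the lattice must cover the
    target grid with the cubic kernel's 4×4×4 support margin.
    """
    shape = tuple(target.shape)
    spacing = np.asarray(target.spacing, dtype=float)
    origin = np.asarray(target.origin, dtype=float)
    ncp = np.array(lattice.control.shape[:3])

    # per-axis dense weight matrices (n_vox, n_cp) — banded, 4 taps each
    W = []
    for a in range(3):
        x = (origin[a] + spacing[a] * np.arange(shape[a]) - lattice.origin[a]) \
            / lattice.spacing[a]
        if x.min() < 1.0 - 1e-9 or x.max() > ncp[a] - 2.0 + 1e-9:
            raise GridError(
                f"lattice does not cover target axis {a} with cubic support: "
                f"coords span [{x.min():.2f}, {x.max():.2f}], "
                f"need [1, {ncp[a] - 2}]"
            )
        base = np.floor(x).astype(np.intp)
        mat = np.zeros((shape[a], ncp[a]))
        for d in range(4):
            mat[np.arange(shape[a]), base + d - 1] = cubic_bspline(
                x - base - (d - 1)
            )
        W.append(mat)

    out = np.einsum("xi,ijkc->xjkc", W[0], lattice.control)
    out = np.einsum("yj,xjkc->xykc", W[1], out)
    out = np.einsum("zk,xykc->xyzc", W[2], out)
    return DeformationField(out, spacing, origin)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _pyramid_level(data: np.ndarray, factor: int, sigma_vox: float) -> np.ndarray:
    """Gaussian anti-aliasing (σ in original voxels) then strided subsampling."""
    if sigma_vox > 0:
        data = ndimage.gaussian_filter(data, sigma_vox)
    return data[::factor, ::factor, ::factor]


def ffd_register(
    fixed: ImageVolume, moving: ImageVolume, cfg: FFDConfig | None = None
) -> DeformationField:
    """Register ``moving`` to ``fixed``; returns the dense pull-back field (mm).

    Stochastic but fully seeded (deterministic per config).  If optimization
    fails to improve the full-grid NMI, the identity field is returned
    instead of a degraded one.  Raises on non-finite similarity.
    """
    cfg = cfg or FFDConfig()
    if fixed.shape != moving.shape or not np.allclose(fixed.spacing, moving.spacing):
        raise GridError("fixed and moving must share a grid after rigid init")
    rng = np.random.default_rng(cfg.seed)
    lattice = BSplineLattice.covering(
        fixed.shape, fixed.spacing, fixed.origin, cfg.grid_spacing_mm
    )

    # Adam state on the control points
    m = np.zeros_like(lattice.control)
    v = np.zeros_like(lattice.control)
    t_step = 0
    b1, b2, eps = 0.9, 0.999, 1e-8

    for level, factor in enumerate(cfg.shrink_factors):
        sigma = cfg.smoothing_sigmas[level]
        f_lvl = _pyramid_level(np.asarray(fixed.data, dtype=np.float64), factor, sigma)
        m_lvl = _pyramid_level(np.asarray(moving.data, dtype=np.float64), factor, sigma)
        spacing = fixed.spacing * factor
        shape = np.array(f_lvl.shape)
        n_vox = int(shape.prod())
        n_samp = min(cfg.samples_per_iteration, n_vox)

        for it in range(cfg.iterations_per_level):
            flat = rng.choice(n_vox, size=n_samp, replace=False)
            idx = np.stack(np.unravel_index(flat, tuple(shape)), axis=-1)
            pts_mm = fixed.origin + idx * spacing
            u, cache = _eval_at_points(lattice, pts_mm)
            coords = idx + u / spacing
            warped, grad = trilinear_sample_multi(m_lvl[None], coords)
            loss, g_b = nmi_loss_grad(f_lvl[tuple(idx.T)], warped[0], cfg.nmi_bins)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite similarity at level {level}, iteration {it}"
                )
            g_pts = g_b[:, None] * grad[0] / spacing  # d(loss)/d(u_mm)
            g_ctrl = _scatter_gradient(lattice, cache, g_pts)
            if cfg.reg_weight > 0:
                # diffusion penalty keeps texture-free regions from drifting
                from .losses import smoothness_grad

                _, g_reg = smoothness_grad(np.moveaxis(lattice.control, -1, 0))
                g_ctrl += cfg.reg_weight * np.moveaxis(g_reg, 0, -1)
            # Adam update
            t_step += 1
            m = b1 * m + (1 - b1) * g_ctrl
            v = b2 * v + (1 - b2) * g_ctrl**2
            mh = m / (1 - b1**t_step)
            vh = v / (1 - b2**t_step)
            lattice.control -= cfg.step_mm * mh / (np.sqrt(vh) + eps)

    fld = bspline_to_dense(
        lattice,
        type("G", (), {"shape": fixed.shape, "spacing": fixed.spacing,
                       "origin": fixed.origin})(),
    )
    fld.frame_id = fixed.frame_id

    # safeguard: never hand back a field that degrades full-grid similarity
    idgrid = np.stack(
        np.meshgrid(*[np.arange(n) for n in fixed.shape], indexing="ij"), axis=-1
    )
    from .fields import trilinear_sample

    warped_full = trilinear_sample(
        np.asarray(moving.data, dtype=np.float64),
        idgrid + fld.displacement / fixed.spacing,
    )
    if nmi_loss(fixed.data, warped_full, cfg.nmi_bins) > nmi_loss(
        fixed.data, moving.data, cfg.nmi_bins
    ):
        return DeformationField.zero(
            fixed.shape, fixed.spacing, fixed.origin, fixed.frame_id
        )
    return fld
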