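"""Weakly supervised displacement-field registration networks.

Three variants of a U-Net displacement regressor, distinguished by their
inputs and losses:

* ``sc``      — fixed + moving scans (2 channels); NMI + smoothness.
* ``msk``     — fixed + moving label images (2 channels, integer codes scaled
  by 1/4); one-hot L1 + smoothness.
* ``sc_msk``  — scans and label images together (4 channels); NMI + one-hot
  L1 + smoothness.

The network regresses dense voxel displacements on the fixed grid (optionally
at half resolution, linearly upsampled); a differentiable trilinear warp
resamples the moving inputs, losses are evaluated at full resolution, and the
whole chain is backpropagated by hand (see :mod:`dosewarp.nn`).  Training uses
Adam with a stepped learning-rate schedule (0.0005 × 0.7 every 10 epochs by
default) and keeps the checkpoint with the best validation measure — mean
organ Dice for the label-aware variants, total validation loss for ``sc``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield, replace

import numpy as np

from .fields import DeformationField, trilinear_sample_multi, warp
from .grids import ImageVolume, LabelVolume, ORGAN_LABELS
from .losses import (
    VARIANT_WEIGHTS,
    l1_grad,
    nmi_loss_grad,
    one_hot,
    smoothness_grad,
)
from .metrics import dsc
from .nn import Adam, UNet3D, Upsample2
from .phantom import GroundTruthPair
from .preprocess import clip_normalize

__all__ = [
    "RegNetConfig",
    "RegPair",
    "SplitPlan",
    "build_network",
    "train",
    "register",
    "make_splits",
    "learning_rate",
]

_VARIANT_CHANNELS = {"sc": 2, "msk": 2, "sc_msk": 4}


@dataclass
class RegNetConfig:
    """Architecture, loss-weight and schedule configuration."""

    variant: str = "sc_msk"
    enc_channels: tuple = (16, 32, 32, 32)
    dec_channels: tuple = (32, 32, 32)
    final_channels: tuple = (16, 16)
    down_factor: int = 2  # field predicted at 1/df resolution, upsampled
    weights: dict = dfield(default_factory=dict)  # overrides of VARIANT_WEIGHTS
    nmi_bins: int = 32
    lr_init: float = 5e-4
    lr_gamma: float = 0.7
    lr_step_epochs: int = 10
    epochs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in _VARIANT_CHANNELS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.down_factor < 1 or self.down_factor & (self.down_factor - 1):
            raise ValueError("down_factor must be a power of two")

    @property
    def in_channels(self) -> int:
        return _VARIANT_CHANNELS[self.variant]

    def loss_weights(self) -> dict:
        w = dict(VARIANT_WEIGHTS[self.variant])
        w.update(self.weights)
        return w


def learning_rate(cfg: RegNetConfig, epoch: int) -> float:
    """Stepped schedule: lr_init × lr_gamma^⌊epoch / step⌋."""
    return cfg.lr_init * cfg.lr_gamma ** (epoch // cfg.lr_step_epochs)


@dataclass
class RegPair:
    """One fixed/moving pair prepared for training or inference.

    Images are expected normalized to [0, 1] (see
    :func:`dosewarp.preprocess.clip_normalize`); labels keep integer codes.
    """

    fixed: ImageVolume
    moving: ImageVolume
    fixed_labels: LabelVolume | None = None
    moving_labels: LabelVolume | None = None
    subject_id: str = ""

    @classmethod
    def from_phantom(cls, pair: GroundTruthPair, subject_id: str = "") -> "RegPair":
        return cls(
            fixed=clip_normalize(pair.planning_image),
            moving=clip_normalize(pair.daily_image),
            fixed_labels=pair.planning_labels,
            moving_labels=pair.daily_labels,
            subject_id=subject_id,
        )


class RegNet:
    """U-Net displacement regressor wrapper handling input stacking,
    optional half-resolution prediction and unit conversion."""

    def __init__(self, cfg: RegNetConfig):
        self.cfg = cfg
        self.unet = UNet3D(
            cin=cfg.in_channels,
            enc=cfg.enc_channels,
            dec=cfg.dec_channels,
            final=cfg.final_channels,
            seed=cfg.seed,
        )
        self._ups = [Upsample2() for _ in range(cfg.down_factor.bit_length() - 1)]

    # -- plumbing ----------------------------------------------------------
    def inputs_for(self, pair: RegPair) -> np.ndarray:
        v = self.cfg.variant
        chans = []
        if v in ("sc", "sc_msk"):
            chans += [pair.fixed.data, pair.moving.data]
        if v in ("msk", "sc_msk"):
            if pair.fixed_labels is None or pair.moving_labels is None:
                raise ValueError(f"variant {v!r} requires label volumes")
            chans += [pair.fixed_labels.data / 4.0, pair.moving_labels.data / 4.0]
        return np.stack(chans).astype(np.float32)

    def _downsample(self, x: np.ndarray) -> np.ndarray:
        df = self.cfg.down_factor
        while df > 1:
            C, X, Y, Z = x.shape
            x = x.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2).mean(axis=(2, 4, 6))
            df //= 2
        return x

    def forward_field(self, x: np.ndarray) -> np.ndarray:
        """Full-resolution (3, X, Y, Z) displacement in voxel units."""
        f = self.unet.forward(self._downsample(x))
        for up in self._ups:
            f = up.forward(f)
        return f

    def backward_field(self, g: np.ndarray) -> None:
        for up in reversed(self._ups):
            g = up.backward(g)
        self.unet.backward(g)

    def predict(self, pair: RegPair) -> DeformationField:
        u_vox = self.forward_field(self.inputs_for(pair))
        fixed = pair.fixed
        disp = np.moveaxis(u_vox.astype(np.float64), 0, -1) * fixed.spacing
        return DeformationField(disp, fixed.spacing, fixed.origin, fixed.frame_id)

    # -- checkpointing ----------------------------------------------------
    def get_weights(self):
        return self.unet.get_weights()

    def set_weights(self, w):
        self.unet.set_weights(w)


def build_network(cfg: RegNetConfig) -> RegNet:
    """Construct the (untrained) registration network for a config."""
    return RegNet(cfg)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

_IDX_CACHE: dict = {}


def _index_grid(shape) -> np.ndarray:
    if shape not in _IDX_CACHE:
        _IDX_CACHE[shape] = np.stack(
            np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=0
        ).astype(np.float32)
    return _IDX_CACHE[shape]


def _cached_one_hot(lab: LabelVolume) -> np.ndarray:
    oh = getattr(lab, "_one_hot", None)
    if oh is None:
        oh = one_hot(lab.data)
        lab._one_hot = oh
    return oh


def _pair_loss(net: RegNet, pair: RegPair, backprop: bool = True):
    """Forward pass, loss components, and (optionally) backprop into the net."""
    cfg = net.cfg
    w = cfg.loss_weights()
    x = net.inputs_for(pair)
    u = net.forward_field(x)
    shape = u.shape[1:]
    coords = np.moveaxis(_index_grid(shape) + u, 0, -1)

    # stack every channel that must be resampled: [moving image?, one-hot...]
    chans = []
    if "nmi" in w:
        chans.append(pair.moving.data.astype(np.float32))
    if "l1" in w:
        m_oh = _cached_one_hot(pair.moving_labels)
        chans.extend(m_oh)
    stack = np.stack(chans)
    warped, grads = trilinear_sample_multi(stack, coords)

    comps: dict = {}
    du = np.zeros_like(u, dtype=np.float32)
    ci = 0
    if "nmi" in w:
        l_nmi, gb = nmi_loss_grad(pair.fixed.data, warped[ci], bins=cfg.nmi_bins)
        comps["nmi"] = l_nmi
        du += w["nmi"] * np.moveaxis(
            gb[..., None].astype(np.float32) * grads[ci], -1, 0
        )
        ci += 1
    if "l1" in w:
        f_oh = _cached_one_hot(pair.fixed_labels)
        l_l1, g_oh = l1_grad(f_oh, warped[ci:])
        comps["l1"] = l_l1
        gl = (g_oh[..., None].astype(np.float32) * grads[ci:]).sum(axis=0)
        du += w["l1"] * np.moveaxis(gl, -1, 0)
    l_s, gs = smoothness_grad(u)
    comps["smooth"] = l_s
    du += w["smooth"] * gs.astype(np.float32)

    total = float(sum(w[k] * comps[k] for k in comps))
    if backprop:
        net.backward_field(du)
    return total, comps


def _val_metric(net: RegNet, val_pairs) -> tuple:
    """(metric, higher_is_better): mean organ DSC for label-aware variants,
    negated mean loss for sc."""
    cfg = net.cfg
    if cfg.variant == "sc":
        losses = [_pair_loss(net, p, backprop=False)[0] for p in val_pairs]
        return -float(np.mean(losses)), "val_loss"
    scores = []
    for p in val_pairs:
        fld = net.predict(p)
        wl = warp(p.moving_labels, fld)
        scores.append(
            np.mean(
                [dsc(wl.data == c, p.fixed_labels.data == c)
                 for c in ORGAN_LABELS.values()]
            )
        )
    return float(np.mean(scores)), "val_mean_dsc"


def train(cfg: RegNetConfig, pairs, val_pairs, verbose: bool = False):
    """Train a variant; returns (best-weights network, history rows).

    History rows are dicts with epoch, lr, mean train loss, per-component
    means and the validation measure.  The returned network carries the
    weights of the epoch with the best validation measure.
    """
    if not pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    net = build_network(cfg)
    opt = Adam(net.unet.params)
    rng = np.random.default_rng(cfg.seed)
    history = []
    best = (-np.inf, None, -1)
    for epoch in range(cfg.epochs):
        lr = learning_rate(cfg, epoch)
        order = rng.permutation(len(pairs))
        tot, comp_sums = [], {}
        for i in order:
            net.unet.zero_grad()
            t, comps = _pair_loss(net, pairs[i])
            if not np.isfinite(t):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, pair {i}: {comps}"
                )
            opt.step(lr)
            tot.append(t)
            for k, v in comps.items():
                comp_sums[k] = comp_sums.get(k, 0.0) + v
        metric, metric_name = _val_metric(net, val_pairs)
        row = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(tot)),
            metric_name: metric if metric_name != "val_loss" else -metric,
        }
        row.update({f"train_{k}": v / len(pairs) for k, v in comp_sums.items()})
        history.append(row)
        if metric > best[0]:
            best = (metric, net.get_weights(), epoch)
        if verbose:
            print(
                f"epoch {epoch:3d} lr {lr:.2e} loss {row['train_loss']:.4f} "
                f"{metric_name} {row[metric_name]:.4f}"
            )
    net.set_weights(best[1])
    net.best_epoch = best[2]
    return net, history


def register(net: RegNet, fixed: ImageVolume, moving: ImageVolume,
             fixed_labels: LabelVolume | None = None,
             moving_labels: LabelVolume | None = None) -> DeformationField:
    """Infer the deformation field for one fixed/moving pair."""
    return net.predict(
        RegPair(fixed=fixed, moving=moving,
                fixed_labels=fixed_labels, moving_labels=moving_labels)
    )


# ---------------------------------------------------------------------------
# subject-level stratified splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Three folds of subject-level train/validation/test partitions."""

    folds: list  # list of {"train": [...], "val": [...], "test": [...]}

    def check(self) -> None:
        for f in self.folds:
            ids = f["train"] + f["val"] + f["test"]
            if len(ids) != len(set(ids)):
                raise ValueError("subject appears in two partitions of a fold")


def _largest_remainder(total: int, fractions) -> list:
    raw = [total * f for f in fractions]
    out = [int(np.floor(r)) for r in raw]
    rem = total - sum(out)
    order = np.argsort([o - r for o, r in zip(out, raw)])
    for i in order[:rem]:
        out[i] += 1
    return out


def make_splits(subjects, seed: int = 0, n_folds: int = 3,
                fractions=(0.70, 0.15, 0.15)) -> SplitPlan:
    """Random subject-level 70/15/15 splits, stratified.

    ``subjects`` is a mapping id → stratum key (e.g. a tuple of
    images-per-subject class and scanner class) or an iterable of ids (single
    stratum).  All images of a subject follow its partition.
    """
    if not isinstance(subjects, dict):
        subjects = {s: 0 for s in subjects}
    ids = sorted(subjects)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 subjects to split")
    strata: dict = {}
    for s in ids:
        strata.setdefault(subjects[s], []).append(s)
    small = [k for k, v in strata.items() if len(v) < 3]
    if small:
        warnings.warn(f"strata with < 3 subjects: {small}", stacklevel=2)

    n_train, n_val, n_test = _largest_remainder(n, fractions)
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_folds):
        parts = {"train": [], "val": [], "test": []}
        # per-stratum proportional quotas, then greedy fix-up to global sizes
        for members in strata.values():
            members = list(members)
            rng.shuffle(members)
            q = _largest_remainder(len(members), fractions)
            parts["train"] += members[: q[0]]
            parts["val"] += members[q[0] : q[0] + q[1]]
            parts["test"] += members[q[0] + q[1] :]
        targets = {"train": n_train, "val": n_val, "test": n_test}
        over = [k for k in parts if len(parts[k]) > targets[k]]
        under = [k for k in parts if len(parts[k]) < targets[k]]
        while over and under:
            src, dst = over[0], under[0]
            parts[dst].append(parts[src].pop())
            over = [k for k in parts if len(parts[k]) > targets[k]]
            under = [k for k in parts if len(parts[k]) < targets[k]]
        folds.append({k: sorted(v) for k, v in parts.items()})
    plan = SplitPlan(folds)
    plan.check()
    return plan
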