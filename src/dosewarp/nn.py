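"""Minimal 3D convolutional network stack with explicit backpropagation.

Implements exactly the pieces a VoxelMorph-style displacement-field U-Net
needs — 3×3×3 same-padding convolutions (im2col + BLAS), leaky ReLU, 2×
average pooling, separable linear 2× upsampling, skip concatenation, and an
Adam optimizer — in float32 numpy.  Each layer caches its forward
intermediates and implements ``backward(grad_out) -> grad_in`` accumulating
parameter gradients, so a full training step is a hand-chained
forward/backward pass.  Everything is seeded and CPU-deterministic.

Arrays are channel-first: ``(C, X, Y, Z)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "LeakyReLU", "AvgPool2", "Upsample2", "UNet3D", "Adam"]


class Conv3d:
    """3×3×3 convolution, stride 1, same (zero) padding."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 init_scale: float | None = None):
        self.cin, self.cout = cin, cout
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / (cin * 27))
        self.W = rng.normal(0.0, scale, size=(cin * 27, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: (C, X, Y, Z) padded -> (X*Y*Z, C*27)
        from numpy.lib.stride_tricks import sliding_window_view

        win = sliding_window_view(x, (3, 3, 3), axis=(1, 2, 3))
        # win: (C, X, Y, Z, 3, 3, 3) -> (X, Y, Z, C, 3, 3, 3)
        win = np.moveaxis(win, 0, 3)
        return np.ascontiguousarray(win).reshape(-1, self.cin * 27)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape[1:]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        col = self._im2col(xp)
        self._cache = col
        out = col @ self.W + self.b
        X, Y, Z = self._shape
        return np.moveaxis(out.reshape(X, Y, Z, self.cout), -1, 0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        X, Y, Z = self._shape
        g2 = np.moveaxis(g, 0, -1).reshape(-1, self.cout).astype(np.float32)
        self.gW += self._cache.T @ g2
        self.gb += g2.sum(axis=0)
        dcol = (g2 @ self.W.T).reshape(X, Y, Z, self.cin, 3, 3, 3)
        dxp = np.zeros((self.cin, X + 2, Y + 2, Z + 2), dtype=np.float32)
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    dxp[:, a : a + X, b : b + Y, c : c + Z] += np.moveaxis(
                        dcol[..., a, b, c], -1, 0
                    )
        self._cache = None
        return dxp[:, 1:-1, 1:-1, 1:-1]


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.slope * g, g)


class AvgPool2:
    """2× average pooling along all three spatial axes (dims must be even)."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, X, Y, Z = x.shape
        self._shape = x.shape
        return x.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2).mean(axis=(2, 4, 6))

    def backward(self, g: np.ndarray) -> np.ndarray:
        C, X, Y, Z = self._shape
        out = np.empty(self._shape, dtype=np.float32)
        rep = (g / 8.0).astype(np.float32)
        out.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2)[:] = rep[
            :, :, None, :, None, :, None
        ]
        return out


def _lin_up_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Linear 2× upsampling along one axis: out[2i]=x[i], out[2i+1]=(x[i]+x[i+1])/2
    with edge clamping."""
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    out = np.empty((2 * n,) + x.shape[1:], dtype=x.dtype)
    out[0::2] = x
    nxt = np.concatenate([x[1:], x[-1:]], axis=0)
    out[1::2] = 0.5 * (x + nxt)
    return np.moveaxis(out, 0, axis)


def _lin_up_axis_T(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_lin_up_axis`."""
    g = np.moveaxis(g, axis, 0)
    ge, go = g[0::2], g[1::2]  # even (copy) and odd (average) taps
    n = ge.shape[0]
    out = ge.astype(np.float32).copy()
    out += 0.5 * go
    out[1:] += 0.5 * go[:-1]
    out[-1] += 0.5 * go[-1]  # clamped neighbour at the edge
    return np.moveaxis(out, 0, axis)


class Upsample2:
    """Separable linear 2× upsampling of all spatial axes."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        for ax in (1, 2, 3):
            x = _lin_up_axis(x, ax)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for ax in (3, 2, 1):
            g = _lin_up_axis_T(g, ax)
        return g


class UNet3D:
    """U-Net regressing a 3-channel displacement field from stacked inputs.

    One conv+LeakyReLU block per encoder level (2× pooled between levels),
    mirrored decoder with skip concatenation, a few full-resolution refinement
    convolutions, and a small-initialized flow head so training starts near
    the identity transform.
    """

    def __init__(self, cin: int, enc=(16, 32, 32, 32), dec=(32, 32, 32),
                 final=(16, 16), seed: int = 0):
        if len(dec) != len(enc) - 1:
            raise ValueError("dec must have len(enc) - 1 levels")
        rng = np.random.default_rng(seed)
        self.enc_convs, self.enc_act = [], []
        c = cin
        for ch in enc:
            self.enc_convs.append(Conv3d(c, ch, rng))
            self.enc_act.append(LeakyReLU())
            c = ch
        self.pools = [AvgPool2() for _ in range(len(enc) - 1)]
        self.ups = [Upsample2() for _ in range(len(enc) - 1)]
        self.dec_convs, self.dec_act = [], []
        c = enc[-1]
        for i, ch in enumerate(dec):
            skip = enc[len(enc) - 2 - i]
            self.dec_convs.append(Conv3d(c + skip, ch, rng))
            self.dec_act.append(LeakyReLU())
            c = ch
        self.final_convs, self.final_act = [], []
        for ch in final:
            self.final_convs.append(Conv3d(c, ch, rng))
            self.final_act.append(LeakyReLU())
            c = ch
        self.flow = Conv3d(c, 3, rng, init_scale=1e-4)
        self.levels = len(enc)

    @property
    def params(self):
        out = []
        for layer in (
            self.enc_convs + self.dec_convs + self.final_convs + [self.flow]
        ):
            out.extend(layer.params)
        return out

    def check_shape(self, shape) -> None:
        div = 2 ** (self.levels - 1)
        bad = {ax: (div - s % div) % div for ax, s in enumerate(shape) if s % div}
        if bad:
            raise ValueError(
                f"grid {tuple(shape)} not divisible by {div}; pad axes by {bad}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.check_shape(x.shape[1:])
        x = x.astype(np.float32)
        skips = []
        for i, (conv, act) in enumerate(zip(self.enc_convs, self.enc_act)):
            x = act.forward(conv.forward(x))
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x)
        self._skip_ch = [s.shape[0] for s in skips]
        for i, (conv, act) in enumerate(zip(self.dec_convs, self.dec_act)):
            x = self.ups[i].forward(x)
            x = np.concatenate([x, skips[len(skips) - 1 - i]], axis=0)
            x = act.forward(conv.forward(x))
        for conv, act in zip(self.final_convs, self.final_act):
            x = act.forward(conv.forward(x))
        return self.flow.forward(x)

    def backward(self, g: np.ndarray) -> None:
        g = self.flow.backward(g.astype(np.float32))
        for conv, act in zip(reversed(self.final_convs), reversed(self.final_act)):
            g = conv.backward(act.backward(g))
        skip_grads = []
        for i in range(len(self.dec_convs) - 1, -1, -1):
            g = self.dec_convs[i].backward(self.dec_act[i].backward(g))
            n_skip = self._skip_ch[len(self._skip_ch) - 1 - i]
            g, gs = g[: g.shape[0] - n_skip], g[g.shape[0] - n_skip :]
            skip_grads.append(gs)
            g = self.ups[i].backward(g)
        for i in range(len(self.enc_convs) - 1, -1, -1):
            if i < len(self.pools):
                g = self.pools[i].backward(g)
                g = g + skip_grads[i]
            g = self.enc_convs[i].backward(self.enc_act[i].backward(g))

    def zero_grad(self) -> None:
        for p, gp in self.params:
            gp[...] = 0.0

    def get_weights(self) -> list:
        return [p.copy() for p, _ in self.params]

    def set_weights(self, weights: list) -> None:
        for (p, _), w in zip(self.params, weights):
            p[...] = w


class Adam:
    """Adam with per-call learning rate (schedules handled by the caller)."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
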