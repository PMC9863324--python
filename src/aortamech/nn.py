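"""Minimal CPU neural-network engine (numpy, float32, manual backprop).

Implements exactly the pieces a U-Net needs — 3x3 same-padding convolution,
instance normalisation, ReLU, 2x2 max-pooling, nearest-neighbour 2x
upsampling, channel concatenation, sigmoid — plus the Adam optimizer.
Convolutions are evaluated as nine offset matmuls (one per kernel tap), which
keeps everything inside BLAS without an im2col buffer. All tensors are
``(N, C, H, W)`` float32; every layer caches what its backward pass needs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "InstanceNorm",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Adam",
    "sigmoid",
    "soft_dice_loss_and_grad",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """3x3 convolution, stride 1, zero same-padding (1x1 supported for shortcuts)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.kernel = kernel
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))  # He init for ReLU nets
        self.w = Param(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)))
        self.b = Param(np.zeros(out_ch))
        self._xpad: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        o = self.w.value.shape[0]
        pad = self.kernel // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        self._xpad = xpad
        out = np.empty((n, o, h * w), dtype=np.float32)
        out[:] = self.b.value[None, :, None]
        for ki in range(self.kernel):
            for kj in range(self.kernel):
                xs = xpad[:, :, ki : ki + h, kj : kj + w].reshape(n, c, h * w)
                out += np.matmul(self.w.value[:, :, ki, kj], xs)
        return out.reshape(n, o, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, o, h, w = dout.shape
        c = self.w.value.shape[1]
        pad = self.kernel // 2
        xpad = self._xpad
        dflat = dout.reshape(n, o, h * w)
        self.b.grad += dflat.sum(axis=(0, 2))
        dxpad = np.zeros_like(xpad)
        for ki in range(self.kernel):
            for kj in range(self.kernel):
                xs = xpad[:, :, ki : ki + h, kj : kj + w].reshape(n, c, h * w)
                # (N,O,HW) @ (N,HW,C) -> (N,O,C), summed over batch
                self.w.grad[:, :, ki, kj] += np.matmul(
                    dflat, xs.transpose(0, 2, 1)
                ).sum(axis=0)
                dxs = np.matmul(self.w.value[:, :, ki, kj].T, dflat)  # (N,C,HW)
                dxpad[:, :, ki : ki + h, kj : kj + w] += dxs.reshape(n, c, h, w)
        self._xpad = None
        return dxpad[:, :, pad : pad + h, pad : pad + w] if pad else dxpad


class InstanceNorm:
    """Per-sample, per-channel normalisation over the spatial axes, with affine."""

    eps = 1e-5

    def __init__(self, channels: int):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv_std * (dxhat - m1 - xhat * m2)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dout, np.float32(0.0))
        self._mask = None
        return out


class MaxPool2:
    """2x2 max pooling, stride 2. Ties propagate gradient to all maxima."""

    params: list[Param] = []

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._cache = (xr, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xr, out = self._cache
        self._cache = None
        mask = xr == out[:, :, :, None, :, None]
        dxr = mask * dout[:, :, :, None, :, None]
        n, c, h2, _, w2, _ = xr.shape
        return dxr.reshape(n, c, h2 * 2, w2 * 2)


class Upsample2:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def soft_dice_loss_and_grad(
    probs: np.ndarray, targets: np.ndarray, smooth: float = 1e-6
) -> tuple[float, np.ndarray]:
    """Per-sample soft Dice loss averaged over the batch, with d(loss)/d(probs).

    loss_i = 1 - (2 sum(p g) + smooth) / (sum(p) + sum(g) + smooth); on hard
    predictions this equals 1 - 2TP/(2TP+FP+FN) up to the smoothing term.
    """
    n = probs.shape[0]
    p = probs.reshape(n, -1).astype(np.float64)
    g = targets.reshape(n, -1).astype(np.float64)
    inter = (p * g).sum(axis=1)
    denom = p.sum(axis=1) + g.sum(axis=1) + smooth
    num = 2.0 * inter + smooth
    loss = float(np.mean(1.0 - num / denom))
    # d/dp_i of -(num/denom): -(2 g denom - num) / denom^2, averaged over batch
    dp = -(2.0 * g * denom[:, None] - num[:, None]) / (denom[:, None] ** 2) / n
    return loss, dp.reshape(probs.shape).astype(np.float32)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
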