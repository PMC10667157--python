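"""Low-level layers with explicit forward/backward passes.

Feature maps are float32 arrays in NHWC (channels-last) layout, which
keeps the im2col gather and scatter cache-friendly (each copied run is a
contiguous pixel's channel vector) and lets the convolution gemm write its
output without a transpose. Each layer caches what its backward pass
needs; caches are overwritten on the next forward call, so a forward must
be paired with at most one backward.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """k x k same-padded convolution (stride 1), He-initialised.

    The weight is ``(k*k*cin, cout)``; row block m holds the kernel tap at
    offset (m // k, m % k). Rather than materialising an im2col matrix,
    the forward pass accumulates one batched matmul per kernel tap over
    strided slabs of the padded input — the same arithmetic with far less
    memory traffic on channels-last data.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout)))
        self.b = Param(np.zeros(cout))
        self._xp: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            self._xp, self._shape = x, x.shape
            y = x.reshape(n * h * w, c) @ self.W.value + self.b.value
            return y.reshape(n, h, w, self.cout)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp, self._shape = xp, x.shape
        y: np.ndarray | None = None
        m = 0
        for ki in range(k):
            for kj in range(k):
                r = xp[:, ki:ki + h, kj:kj + w, :] @ self.W.value[m * c:(m + 1) * c]
                y = r if y is None else y + r
                m += 1
        return y + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        k, p = self.k, self.k // 2
        g2 = gy.reshape(n * h * w, self.cout)
        self.b.grad += g2.sum(axis=0)
        if k == 1:
            self.W.grad += self._xp.reshape(n * h * w, c).T @ g2
            gx = (g2 @ self.W.value.T).reshape(n, h, w, c)
            self._xp = None
            return gx
        xp = self._xp
        dxp = np.zeros_like(xp)
        m = 0
        for ki in range(k):
            for kj in range(k):
                slab = xp[:, ki:ki + h, kj:kj + w, :]
                self.W.grad[m * c:(m + 1) * c] += np.einsum(
                    "nhwc,nhwo->co", slab, gy, optimize=True
                )
                dxp[:, ki:ki + h, kj:kj + w, :] += (
                    g2 @ self.W.value[m * c:(m + 1) * c].T
                ).reshape(n, h, w, c)
                m += 1
        self._xp = None
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling; stores argmax indices for gradient routing and for
    max-unpooling index transfer in the decoder."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = np.stack(
            [x[:, 0::2, 0::2], x[:, 0::2, 1::2], x[:, 1::2, 0::2], x[:, 1::2, 1::2]],
            axis=-1,
        )  # n, h/2, w/2, c, 4
        self.idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return _unpool_scatter(gy, self.idx, self._shape)

    def gather(self, y: np.ndarray) -> np.ndarray:
        """Pick the stored argmax entry from a full-resolution map."""
        yr = np.stack(
            [y[:, 0::2, 0::2], y[:, 0::2, 1::2], y[:, 1::2, 0::2], y[:, 1::2, 1::2]],
            axis=-1,
        )
        return np.take_along_axis(yr, self.idx[..., None], axis=-1)[..., 0]


def _unpool_scatter(v: np.ndarray, idx: np.ndarray, out_shape: tuple) -> np.ndarray:
    n, h, w, c = out_shape
    g = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
    np.put_along_axis(g, idx[..., None], v[..., None], axis=-1)
    out = np.zeros(out_shape, dtype=np.float32)
    out[:, 0::2, 0::2] = g[..., 0]
    out[:, 0::2, 1::2] = g[..., 1]
    out[:, 1::2, 0::2] = g[..., 2]
    out[:, 1::2, 1::2] = g[..., 3]
    return out


class MaxUnpool2d(Layer):
    """Upsampling that places each value at the argmax location recorded by
    a paired :class:`MaxPool2d` (index transfer)."""

    def __init__(self, pool: MaxPool2d):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h2, w2, c = x.shape
        return _unpool_scatter(x, self.pool.idx, (n, 2 * h2, 2 * w2, c))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.pool.gather(gy)


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, 4 * cout)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._x2 = x.reshape(n * h * w, c)
        self._shape = x.shape
        y4 = (self._x2 @ self.W.value).reshape(n, h, w, 2, 2, self.cout)
        out = np.empty((n, 2 * h, 2 * w, self.cout), dtype=np.float32)
        out[:, 0::2, 0::2] = y4[:, :, :, 0, 0]
        out[:, 0::2, 1::2] = y4[:, :, :, 0, 1]
        out[:, 1::2, 0::2] = y4[:, :, :, 1, 0]
        out[:, 1::2, 1::2] = y4[:, :, :, 1, 1]
        return out + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        g4 = np.empty((n, h, w, 2, 2, self.cout), dtype=np.float32)
        g4[:, :, :, 0, 0] = gy[:, 0::2, 0::2]
        g4[:, :, :, 0, 1] = gy[:, 0::2, 1::2]
        g4[:, :, :, 1, 0] = gy[:, 1::2, 0::2]
        g4[:, :, :, 1, 1] = gy[:, 1::2, 1::2]
        g2 = g4.reshape(n * h * w, 4 * self.cout)
        self.W.grad += self._x2.T @ g2
        self.b.grad += gy.sum(axis=(0, 1, 2))
        gx = (g2 @ self.W.value.T).reshape(n, h, w, c)
        self._x2 = None
        return gx


class Maximum(Layer):
    """Element-wise maximum of two feature maps (competitive fusion)."""

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        self._amax = a >= b
        return np.where(self._amax, a, b)

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return gy * self._amax, gy * ~self._amax


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def segmentation_loss(
    logits: np.ndarray,
    target: np.ndarray,
    n_classes: int = 3,
    ce_weight: float = 1.0,
    dice_weight: float = 1.0,
    class_weights: np.ndarray | None = None,
    eps: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Pixel-wise cross-entropy plus macro soft-Dice over the fat classes.

    ``logits`` are (N, H, W, C); ``target`` integer labels (N, H, W).
    Returns ``(loss, dlogits)``. The soft-Dice term averages over classes
    1..n_classes-1 (SAT, VAT), countering the background-dominance class
    imbalance of abdominal slices.
    """
    p = softmax(logits)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, target[..., None].astype(np.intp), 1.0, axis=-1)

    if class_weights is None:
        wpix = np.ones(target.shape + (1,), dtype=np.float32)
    else:
        wpix = np.asarray(class_weights, dtype=np.float32)[target][..., None]
    npix = float(wpix.sum())

    logp = np.log(np.clip(p, 1e-12, None))
    ce = float(-(wpix * onehot * logp).sum() / npix)
    dlog = ce_weight * wpix * (p - onehot) / npix

    fg = list(range(1, n_classes))
    dice_terms = []
    gp = np.zeros_like(p)
    for k in fg:
        pk, yk = p[..., k], onehot[..., k]
        inter = float((pk * yk).sum())
        s = float(pk.sum() + yk.sum()) + eps
        d = (2.0 * inter + eps) / s
        dice_terms.append(d)
        # d(1-d)/dp = -(2 y s - (2 inter + eps)) / s^2
        gp[..., k] = -(2.0 * yk * s - (2.0 * inter + eps)) / (s * s) / len(fg)
    dice_loss = 1.0 - float(np.mean(dice_terms))
    # chain rule through the softmax for the dice term
    dot = (gp * p).sum(axis=-1, keepdims=True)
    dlog += dice_weight * p * (gp - dot)

    return ce_weight * ce + dice_weight * dice_loss, dlog.astype(np.float32)


class Adam:
    """Adaptive-moment optimiser."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
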