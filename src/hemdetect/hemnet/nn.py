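"""Minimal NHWC neural-network layers with explicit forward/backward passes.

Everything runs in float32 NumPy with im2col-style lowering to BLAS matmuls,
which keeps a shallow network trainable on a single CPU core while staying
fully deterministic under a seeded Generator.  Convolutions and pools use
"same" padding relative to the stride: out = ceil(in / stride), with the
total padding split floor-before / rest-after.  Average pools include padded
zeros in the mean (uniform 1/k^2 weights), which only affects border cells.

Large intermediates (im2col matrices, padded gradients) are allocated once
per input shape and reused across batches: freshly mapped pages cost two
orders of magnitude more than warm ones, and a training run touches the
same shapes thousands of times.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def same_pad(size: int, k: int, s: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for same-padding at stride s."""
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return out, total // 2, total - total // 2


class Layer:
    """Base: optionally holds params/grads; forward caches what backward needs."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}
        self._bufs: dict[tuple, np.ndarray] = {}

    def _buf(self, key: str, shape: tuple[int, ...]) -> np.ndarray:
        full = (key, shape)
        buf = self._bufs.get(full)
        if buf is None:
            buf = np.zeros(shape, dtype=F32)
            self._bufs[full] = buf
        return buf

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        stride: int,
        rng: np.random.Generator,
        input_grad: bool = True,
    ):
        super().__init__()
        self.k, self.s, self.c_in, self.c_out = k, stride, c_in, c_out
        self.input_grad = input_grad  # False for a first layer: dx unused
        std = np.sqrt(2.0 / (k * k * c_in))
        self.params["W"] = (rng.standard_normal((k * k * c_in, c_out)) * std).astype(F32)
        self.params["b"] = np.zeros(c_out, dtype=F32)

    def _geometry(self, x_shape: tuple[int, ...]):
        n, h, w, c = x_shape
        oh, pbh, pah = same_pad(h, self.k, self.s)
        ow, pbw, paw = same_pad(w, self.k, self.s)
        return n, h, w, c, oh, ow, pbh, pah, pbw, paw

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c, oh, ow, pbh, pah, pbw, paw = self._geometry(x.shape)
        self._x_shape = x.shape
        xp = self._buf("xp", (n, h + pbh + pah, w + pbw + paw, c))
        xp[:, pbh: pbh + h, pbw: pbw + w, :] = x
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))[:, :: self.s, :: self.s]
        # win: (n, oh, ow, c, k, k) -> cols (n*oh*ow, k*k*c)
        cols = self._buf("cols", (n * oh * ow, self.k * self.k * c))
        cols_v = cols.reshape(n, oh, ow, self.k, self.k, c)
        np.copyto(cols_v, win.transpose(0, 1, 2, 4, 5, 3))
        self._cols = cols
        y = self._buf("y", (n * oh * ow, self.c_out))
        np.matmul(cols, self.params["W"], out=y)
        y += self.params["b"]
        return y.reshape(n, oh, ow, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c, oh, ow, pbh, pah, pbw, paw = self._geometry(self._x_shape)
        dy2 = np.ascontiguousarray(dy, dtype=F32).reshape(n * oh * ow, self.c_out)
        self.grads["W"] = self._cols.T @ dy2
        self.grads["b"] = dy2.sum(axis=0)
        if not self.input_grad:
            return None
        dxp = self._buf("dxp", (n, h + pbh + pah, w + pbw + paw, c))
        dxp[...] = 0.0
        # per-tap, per-sample GEMMs: scattering a full (positions x k x k
        # x c) gradient matrix by fancy slicing touches one cache line per
        # element, and a whole-batch per-tap GEMM re-reads the 4·P·F-byte
        # gradient once per tap; one sample's gradient fits in L2 instead
        dblock = self._buf("dblock", (oh * ow, c))
        weight = self.params["W"]
        taps = [
            (ki, kj, weight[(ki * self.k + kj) * c: (ki * self.k + kj + 1) * c, :].T)
            for ki in range(self.k)
            for kj in range(self.k)
        ]
        dy4 = dy2.reshape(n, oh * ow, self.c_out)
        s = self.s
        for i in range(n):
            dy_i = dy4[i]
            for ki, kj, w_tap in taps:
                np.matmul(dy_i, w_tap, out=dblock)
                dxp[i, ki: ki + s * oh: s, kj: kj + s * ow: s, :] += dblock.reshape(
                    oh, ow, c
                )
        dx = self._buf("dx", (n, h, w, c))
        np.copyto(dx, dxp[:, pbh: pbh + h, pbw: pbw + w, :])
        return dx


class AvgPool2D(Layer):
    def __init__(self, k: int, stride: int):
        super().__init__()
        self.k, self.s = k, stride

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        self._x_shape = x.shape
        oh, pbh, pah = same_pad(h, self.k, self.s)
        ow, pbw, paw = same_pad(w, self.k, self.s)
        xp = self._buf("xp", (n, h + pbh + pah, w + pbw + paw, c))
        xp[:, pbh: pbh + h, pbw: pbw + w, :] = x
        y = self._buf("y", (n, oh, ow, c))
        y[...] = 0.0
        s = self.s
        for ki in range(self.k):
            for kj in range(self.k):
                y += xp[:, ki: ki + s * oh: s, kj: kj + s * ow: s, :]
        y *= F32(1.0 / (self.k * self.k))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        oh, pbh, pah = same_pad(h, self.k, self.s)
        ow, pbw, paw = same_pad(w, self.k, self.s)
        dxp = self._buf("dxp", (n, h + pbh + pah, w + pbw + paw, c))
        dxp[...] = 0.0
        g = self._buf("g", dy.shape)
        np.multiply(dy, F32(1.0 / (self.k * self.k)), out=g)
        s = self.s
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, ki: ki + s * oh: s, kj: kj + s * ow: s, :] += g
        dx = self._buf("dx", (n, h, w, c))
        np.copyto(dx, dxp[:, pbh: pbh + h, pbw: pbw + w, :])
        return dx


class ReLU(Layer):
    def _mask_buf(self, shape: tuple[int, ...]) -> np.ndarray:
        full = ("mask", shape)
        buf = self._bufs.get(full)
        if buf is None:
            buf = np.zeros(shape, dtype=bool)
            self._bufs[full] = buf
        return buf

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = self._mask_buf(x.shape)
        np.greater(x, 0, out=mask)
        self._mask = mask
        y = self._buf("y", x.shape)
        np.multiply(x, mask, out=y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self._buf("dx", dy.shape)
        np.multiply(dy, self._mask, out=dx)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=F32)
        self.params["beta"] = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = self._buf("xhat", x.shape)
        np.subtract(x, mean.astype(F32), out=xhat)
        xhat *= inv
        self._inv, self._axes = inv, axes
        y = self._buf("y", x.shape)
        np.multiply(xhat, self.params["gamma"], out=y)
        y += self.params["beta"]
        self._xhat = xhat
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = self._axes
        xhat = self._xhat
        spec = "nhwc,nhwc->c" if dy.ndim == 4 else "nc,nc->c"
        self.grads["gamma"] = np.einsum(spec, dy, xhat, optimize=False)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        dx = self._buf("dx", dy.shape)
        np.multiply(dy, g, out=dx)                      # dxhat
        m = dx.size // dx.shape[-1]
        mean_dxhat = dx.sum(axis=axes) / F32(m)
        mean_dxhat_xhat = np.einsum(spec, dx, xhat, optimize=False) / F32(m)
        dx -= mean_dxhat
        # dx -= xhat * mean_dxhat_xhat, without a full-size temporary
        scratch = self._buf("scratch", dy.shape)
        np.multiply(xhat, mean_dxhat_xhat, out=scratch)
        dx -= scratch
        dx *= self._inv
        return dx


class Dense(Layer):
    """Flatten + fully-connected layer."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.params["W"] = (rng.standard_normal((n_in, n_out)) * std).astype(F32)
        self.params["b"] = np.zeros(n_out, dtype=F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x_shape = x.shape
        self._xf = np.ascontiguousarray(x, dtype=F32).reshape(x.shape[0], -1)
        return self._xf @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=F32)
        self.grads["W"] = self._xf.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return (dy @ self.params["W"].T).reshape(self._x_shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood; labels are integer class indices."""
    n = probs.shape[0]
    return float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())


def softmax_ce_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(mean CE)/d(logits) for a softmax + cross-entropy head."""
    n = probs.shape[0]
    g = probs.copy()
    g[np.arange(n), labels] -= 1.0
    return (g / n).astype(F32)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, layers: list[Layer], lr: float, momentum: float = 0.9):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.momentum = momentum
        self.velocity = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        if self.lr == 0:
            return
        for layer, vel in zip(self.layers, self.velocity):
            for k, p in layer.params.items():
                v = vel[k]
                v *= self.momentum
                v -= self.lr * layer.grads[k]
                p += v
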