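"""Minimal trainable CNN building blocks in numpy.

Implements exactly what the dual-patch classifier needs — 3x3 same-padding
convolution, ReLU, 2x2/stride-2 max pooling, dense layers, inverted dropout,
a softmax cross-entropy head with optional per-class weights, and Adam — with
explicit forward/backward passes.

Activations are channels-last ``(batch, height, width, channels)`` float32
throughout, so convolution reduces to an im2col gather plus one BLAS GEMM and
flattening is free. The gather/scatter and pooling inner loops are compiled
with numba when available (pure-numpy fallbacks otherwise). Given a seeded
``numpy.random.Generator`` every run is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco


# ---------------------------------------------------------------------------
# Compiled inner loops (channels-last layouts)
# ---------------------------------------------------------------------------
# column index convention: k = (u*3 + v)*C + c for kernel offset (u, v),
# input channel c — the innermost c runs over contiguous memory.


@njit(fastmath=True, cache=True)
def _im2col_k(xp, cols, h, w):  # pragma: no cover - compiled
    b, c = xp.shape[0], xp.shape[3]
    for n in range(b):
        for i in range(h):
            for j in range(w):
                k = 0
                for u in range(3):
                    for v in range(3):
                        for ch in range(c):
                            cols[n, i, j, k] = xp[n, i + u, j + v, ch]
                            k += 1


@njit(fastmath=True, cache=True)
def _col2im_k(dcols, dxp, h, w):  # pragma: no cover - compiled
    b, c = dxp.shape[0], dxp.shape[3]
    for n in range(b):
        for i in range(h):
            for j in range(w):
                k = 0
                for u in range(3):
                    for v in range(3):
                        for ch in range(c):
                            dxp[n, i + u, j + v, ch] += dcols[n, i, j, k]
                            k += 1


@njit(fastmath=True, cache=True)
def _pool_fwd_k(x, y, idx):  # pragma: no cover - compiled
    b, h2, w2, c = y.shape
    for n in range(b):
        for i in range(h2):
            for j in range(w2):
                for ch in range(c):
                    best = x[n, 2 * i, 2 * j, ch]
                    code = 0
                    for u in range(2):
                        for v in range(2):
                            val = x[n, 2 * i + u, 2 * j + v, ch]
                            if val > best:
                                best = val
                                code = 2 * u + v
                    y[n, i, j, ch] = best
                    idx[n, i, j, ch] = code


@njit(fastmath=True, cache=True)
def _pool_bwd_k(dy, idx, dx):  # pragma: no cover - compiled
    b, h2, w2, c = dy.shape
    for n in range(b):
        for i in range(h2):
            for j in range(w2):
                for ch in range(c):
                    code = idx[n, i, j, ch]
                    dx[n, 2 * i + code // 2, 2 * j + code % 2, ch] = dy[n, i, j, ch]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, H, W, C) -> (B, H, W, 9C) patch matrix of the zero-padded input."""
    b, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((b, h, w, 9 * c), dtype=np.float32)
    if HAVE_NUMBA:
        _im2col_k(xp, cols, h, w)
    else:
        for u in range(3):
            for v in range(3):
                k = (u * 3 + v) * c
                cols[:, :, :, k : k + c] = xp[:, u : u + h, v : v + w, :]
    return cols


def _col2im(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    b, h, w, c = shape
    dxp = np.zeros((b, h + 2, w + 2, c), dtype=np.float32)
    if HAVE_NUMBA:
        _col2im_k(dcols, dxp, h, w)
    else:
        for u in range(3):
            for v in range(3):
                k = (u * 3 + v) * c
                dxp[:, u : u + h, v : v + w, :] += dcols[:, :, :, k : k + c]
    return dxp[:, 1:-1, 1:-1, :]


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (spatial size preserved).

    Weights are stored as a ``(9*C_in, C_out)`` matrix matching the im2col
    column order, so the whole layer is one GEMM.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out
        self._cols = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = _im2col(x)
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return cols @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self._cols.shape[-1]
        cols2 = self._cols.reshape(-1, k)
        dy2 = dy.reshape(-1, self.c_out)
        self.dw = cols2.T @ dy2
        self.db = dy2.sum(axis=0)
        dcols = dy2 @ self.w.T
        dx = _col2im(dcols.reshape(dy.shape[:3] + (k,)), self._in_shape)
        self._cols = None
        return dx

    def params(self):
        return [("w", self), ("b", self)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling with stride 2; trailing odd rows/columns are dropped.

    The stored argmax makes the backward pass route each gradient to exactly
    one input (ties resolve to the first of the 2x2 window).
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        y = np.empty((b, h2, w2, c), dtype=np.float32)
        idx = np.empty((b, h2, w2, c), dtype=np.uint8)
        if HAVE_NUMBA:
            _pool_fwd_k(x, y, idx)
        else:
            v = x[:, : h2 * 2, : w2 * 2, :].reshape(b, h2, 2, w2, 2, c)
            v = v.transpose(0, 1, 3, 5, 2, 4).reshape(b, h2, w2, c, 4)
            idx = v.argmax(axis=-1).astype(np.uint8)
            y = np.take_along_axis(v, idx[..., None].astype(np.intp), axis=-1)[..., 0]
        if train:
            self._idx, self._in_shape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape, dtype=np.float32)
        if HAVE_NUMBA:
            _pool_bwd_k(dy, self._idx, dx)
        else:
            b, h2, w2, c = dy.shape
            for u in range(2):
                for v in range(2):
                    sel = self._idx == 2 * u + v
                    target = dx[:, u : u + 2 * h2 : 2, v : v + 2 * w2 : 2, :]
                    target[sel] = dy[sel]
        return dx

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(
            np.float32
        )
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        self._x = None
        return dy @ self.w.T

    def params(self):
        return [("w", self), ("b", self)]


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, labels: np.ndarray, sample_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    ll = -np.log(p[np.arange(n), labels] + eps)
    if sample_weights is None:
        sample_weights = np.ones(n)
    wsum = sample_weights.sum()
    loss = float((sample_weights * ll).sum() / wsum)
    if not np.isfinite(loss):
        raise TrainingError(f"non-finite training loss: {loss}")
    grad = p
    grad[np.arange(n), labels] -= 1.0
    grad *= (sample_weights / wsum)[:, None]
    return loss, grad.astype(np.float32)


class Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        # params: list of (attr_name, layer); gradients live on d<attr_name>
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(layer, a)) for a, layer in params]
        self.v = [np.zeros_like(getattr(layer, a)) for a, layer in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (attr, layer) in enumerate(self.params):
            g = getattr(layer, "d" + attr).astype(np.float32)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / b1t
            vh = self.v[i] / b2t
            val = getattr(layer, attr)
            val -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(np.float32)
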