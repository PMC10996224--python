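"""Minimal NumPy layer library with manual backprop.

Only what the dual-branch network needs: 2-D convolution (same padding),
ReLU, 2x2 max pooling, 2x bilinear upsampling, channel concatenation and
global average pooling.  Each layer caches what its backward pass requires;
``backward`` consumes the cache, so forward/backward calls must alternate.

Everything runs in float32; convolutions are lowered to a single GEMM via
im2col, which is the throughput bottleneck on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

DTYPE = np.float32


@dataclass
class Param:
    name: str
    value: np.ndarray
    grad: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.value = np.asarray(self.value, dtype=DTYPE)
        if self.grad is None:
            self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> List[Param]:
        return []


class Conv2d(Layer):
    """kxk convolution, stride 1, zero 'same' padding for odd k."""

    def __init__(self, cin: int, cout: int, k: int, name: str, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = (k - 1) // 2
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(cout))
        self._cols: Optional[np.ndarray] = None
        self._xshape = None

    def params(self):
        return [self.w, self.b]

    def _w2(self) -> np.ndarray:
        # rows of the im2col matrix are ordered [(i, j) offset][input channel]
        return np.ascontiguousarray(
            self.w.value.transpose(0, 2, 3, 1).reshape(self.cout, -1)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, p = self.k, self.pad
        if k == 1:
            cols = x.transpose(1, 0, 2, 3).reshape(c, -1)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            cols = np.empty((c * k * k, n * h * w), dtype=DTYPE)
            r = 0
            for i in range(k):
                for j in range(k):
                    cols[r : r + c] = xp[:, :, i : i + h, j : j + w].transpose(
                        1, 0, 2, 3
                    ).reshape(c, -1)
                    r += c
        self._cols = cols
        self._xshape = (n, c, h, w)
        out = self._w2() @ cols  # (cout, n*h*w)
        out += self.b.value[:, None]
        return out.reshape(self.cout, n, h, w).transpose(1, 0, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.k, self.pad
        cols = self._cols
        self._cols = None
        d2 = np.ascontiguousarray(
            dout.transpose(1, 0, 2, 3).reshape(self.cout, -1), dtype=DTYPE
        )
        self.b.grad += d2.sum(axis=1)
        dw2 = d2 @ cols.T  # (cout, c*k*k)
        self.w.grad += dw2.reshape(self.cout, k, k, c).transpose(0, 3, 1, 2)
        dcols = self._w2().T @ d2  # (c*k*k, n*h*w)
        if k == 1:
            return dcols.reshape(c, n, h, w).transpose(1, 0, 2, 3)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        r = 0
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[r : r + c].reshape(
                    c, n, h, w
                ).transpose(1, 0, 2, 3)
                r += c
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        m = self._mask
        self._mask = None
        return dout * m


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Ties resolve to the first maximum."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        self._idx = idx
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        d4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(d4, self._idx[..., None], dout[..., None].astype(DTYPE), axis=-1)
        self._idx = None
        d4 = d4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(d4).reshape(n, c, h, w)


def _up2_last(x: np.ndarray) -> np.ndarray:
    """2x bilinear upsampling (align_corners=False) along the last axis.

    out[2i] = 0.25*x[i-1] + 0.75*x[i]; out[2i+1] = 0.75*x[i] + 0.25*x[i+1],
    with indices clipped at the edges.
    """
    n = x.shape[-1]
    prev = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    nxt = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    out = np.empty(x.shape[:-1] + (2 * n,), dtype=x.dtype)
    out[..., 0::2] = 0.75 * x + 0.25 * prev
    out[..., 1::2] = 0.75 * x + 0.25 * nxt
    return out


def _down2_last(d: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_up2_last` (exact transpose of the linear map)."""
    d0 = d[..., 0::2]
    d1 = d[..., 1::2]
    dx = (0.75 * (d0 + d1)).astype(DTYPE)
    dx[..., :-1] += 0.25 * d0[..., 1:]
    dx[..., 0] += 0.25 * d0[..., 0]
    dx[..., 1:] += 0.25 * d1[..., :-1]
    dx[..., -1] += 0.25 * d1[..., -1]
    return dx


class BilinearUp2(Layer):
    """2x bilinear upsampling (align_corners=False), a fixed linear map."""

    def forward(self, x):
        x = np.asarray(x, dtype=DTYPE)
        y = _up2_last(x)  # columns
        y = _up2_last(y.swapaxes(-1, -2)).swapaxes(-1, -2)  # rows
        return np.ascontiguousarray(y)

    def backward(self, dout):
        d = _down2_last(np.asarray(dout, dtype=DTYPE).swapaxes(-1, -2)).swapaxes(-1, -2)
        return _down2_last(d)


class GlobalAvgPool(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        self._shape = None
        return (
            np.broadcast_to(dout.astype(DTYPE)[:, :, None, None], (n, c, h, w)) / (h * w)
        ).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def double_conv(cin: int, cout: int, name: str, rng) -> Sequential:
    """The canonical U-Net block: two 3x3 convolutions, each with ReLU."""
    return Sequential(
        Conv2d(cin, cout, 3, f"{name}.conv1", rng),
        ReLU(),
        Conv2d(cout, cout, 3, f"{name}.conv2", rng),
        ReLU(),
    )
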