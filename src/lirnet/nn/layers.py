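"""Minimal CNN building blocks with explicit backpropagation.

Arrays are NCHW. Every layer caches whatever its backward pass needs during
``forward``, so one layer instance serves exactly one position in a network
and one forward/backward cycle at a time. Parameter gradients accumulate
until :meth:`Layer.zero_grad`.

The blocks here are deliberately small: same-padded convolutions, ReLU,
identity-mapping residual blocks, a dot-product nonlocal (self-attention)
block and nearest-neighbor upsampling — exactly what the density-map
regression network is assembled from.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "ResidualBlock",
    "NonLocalBlock",
    "Upsample2x",
]


class Param:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded ``ksize`` x ``ksize`` convolution with He-normal init.

    ``stride=2`` halves even spatial dimensions (used for downsampling).
    ``zero_init=True`` starts the layer as the zero map; the residual
    projection of the nonlocal block uses this so the block begins as the
    identity.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        ksize: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
        zero_init: bool = False,
    ):
        rng = np.random.default_rng() if rng is None else rng
        fan_in = cin * ksize * ksize
        if zero_init:
            w = np.zeros((cout, cin, ksize, ksize), dtype=dtype)
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, ksize, ksize))
            w = w.astype(dtype)
        self.w = Param(w)
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.ksize = ksize
        self.stride = stride
        self.pad = ksize // 2

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.ksize, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        self._cols = cols
        self._xshape = x.shape
        self._oshape = (n, ho, wo)
        cout = self.w.data.shape[0]
        out = cols @ self.w.data.reshape(cout, -1).T + self.b.data
        return out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, ho, wo = self._oshape
        _, cin, h, w = self._xshape
        k, s, p = self.ksize, self.stride, self.pad
        cout = self.w.data.shape[0]
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.w.grad += (dmat.T @ self._cols).reshape(self.w.data.shape)
        self.b.grad += dmat.sum(axis=0)
        dcols = dmat @ self.w.data.reshape(cout, -1)
        dwin = dcols.reshape(n, ho, wo, cin, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, cin, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for u in range(k):
            for v in range(k):
                dxp[:, :, u : u + s * (ho - 1) + 1 : s, v : v + s * (wo - 1) + 1 : s] += dwin[
                    :, :, :, :, u, v
                ]
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, x.dtype.type(0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, dout.dtype.type(0))


class ReLUWithRecovery(Layer):
    """ReLU whose dead units can recover.

    Forward is exactly ReLU. Backward uses the usual mask where the input is
    positive, but additionally lets gradient through wherever the unit is
    dead *and* the loss would decrease if the output rose (negative upstream
    gradient). Used at the network head: with losses whose background term
    pushes the whole map down at constant slope, a plain output ReLU has an
    absorbing all-zero state that blocks every gradient in the network; this
    subgradient choice makes that state escapable without changing what the
    layer computes.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, x.dtype.type(0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        allow = self._mask | (dout < 0)
        return np.where(allow, dout, dout.dtype.type(0))


class ResidualBlock(Layer):
    """Two same-channel 3x3 convolutions with an identity skip: relu(x + F(x))."""

    def __init__(self, ch: int, rng: np.random.Generator | None = None, dtype=np.float32):
        self.conv1 = Conv2d(ch, ch, 3, 1, rng, dtype)
        self.act1 = ReLU()
        self.conv2 = Conv2d(ch, ch, 3, 1, rng, dtype)
        self.act2 = ReLU()

    def params(self) -> list[Param]:
        return self.conv1.params() + self.conv2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.act1.forward(self.conv1.forward(x)))
        return self.act2.forward(x + h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.act2.backward(dout)
        dh = self.conv1.backward(self.act1.backward(self.conv2.backward(d)))
        return d + dh


class NonLocalBlock(Layer):
    """Residual self-attention over all spatial positions of a feature map.

    The pairwise function is the plain dot product between embedded
    positions, normalized by the number of positions; the aggregated values
    are projected back and added to the input. The output projection is
    zero-initialized so a freshly built block is the identity map, which
    keeps early training stable and makes the with/without-attention
    ablation start from identical predictions.
    """

    def __init__(self, ch: int, rng: np.random.Generator | None = None, dtype=np.float32):
        rng = np.random.default_rng() if rng is None else rng
        self.cem = max(ch // 2, 1)
        self.theta = Conv2d(ch, self.cem, 1, 1, rng, dtype)
        self.phi = Conv2d(ch, self.cem, 1, 1, rng, dtype)
        self.g = Conv2d(ch, self.cem, 1, 1, rng, dtype)
        self.proj = Conv2d(self.cem, ch, 1, 1, rng, dtype, zero_init=True)

    def params(self) -> list[Param]:
        return (
            self.theta.params() + self.phi.params() + self.g.params() + self.proj.params()
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        pnum = h * w
        t = self.theta.forward(x).reshape(n, self.cem, pnum)
        p_ = self.phi.forward(x).reshape(n, self.cem, pnum)
        g_ = self.g.forward(x).reshape(n, self.cem, pnum)
        att = np.einsum("nci,ncj->nij", t, p_) / pnum
        y = np.einsum("nij,ncj->nci", att, g_)
        self._cache = (t, p_, g_, att, (n, c, h, w))
        z = self.proj.forward(np.ascontiguousarray(y).reshape(n, self.cem, h, w))
        return x + z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        t, p_, g_, att, (n, c, h, w) = self._cache
        pnum = h * w
        dy = self.proj.backward(dout).reshape(n, self.cem, pnum)
        datt = np.einsum("nci,ncj->nij", dy, g_)
        dg = np.einsum("nij,nci->ncj", att, dy)
        dt = np.einsum("nij,ncj->nci", datt, p_) / pnum
        dp = np.einsum("nij,nci->ncj", datt, t) / pnum
        dx = dout.copy()
        dx += self.theta.backward(np.ascontiguousarray(dt).reshape(n, self.cem, h, w))
        dx += self.phi.backward(np.ascontiguousarray(dp).reshape(n, self.cem, h, w))
        dx += self.g.backward(np.ascontiguousarray(dg).reshape(n, self.cem, h, w))
        return dx


class Upsample2x(Layer):
    """Nearest-neighbor x2 upsampling (sum-pooling in the backward pass)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dout.shape
        return dout.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
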