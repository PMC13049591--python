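"""Convolution and pooling layers (im2col via stride tricks).

``Conv3D`` treats input as ``(N, C, D, H, W)`` with same padding relative to
the stride (output size ``ceil(dim / stride)``). Max pooling uses ceil-mode
windows (right-padded with -inf), so odd axes survive repeated halving — a
requirement for the stride/pool cascade on a 19-channel, 500-sample input.
EEGNet-specific pieces (depthwise spatial / temporal convolutions, average
pooling over time) operate on ``(N, F, C, T)`` / ``(N, F, T)`` tensors.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Layer, glorot

__all__ = [
    "Conv3D", "MaxPool3D", "Conv2D", "DepthwiseSpatialConv",
    "DepthwiseTemporalConv", "PointwiseConv", "AvgPoolTime",
]


def _same_pad(size: int, k: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for same padding."""
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + k - size, 0)
    before = total // 2
    return out, before, total - before


class Conv3D(Layer):
    """3-D convolution with same padding; kernel ``(kd, kh, kw)``."""

    def __init__(
        self,
        out_channels: int,
        kernel: tuple[int, int, int] = (3, 3, 3),
        stride: tuple[int, int, int] = (1, 1, 1),
        name: str = "conv3d",
    ) -> None:
        super().__init__()
        self.cout = out_channels
        self.kernel = kernel
        self.stride = stride
        self.name = name

    def build(self, in_shape, rng):
        cin, d, h, w = in_shape
        if min(d, h, w) < 1:
            raise ValueError(f"{self.name}: spatial input {in_shape} collapsed to zero")
        kd, kh, kw = self.kernel
        fan_in = cin * kd * kh * kw
        self.p = {
            "W": glorot(rng, (self.cout, cin, kd, kh, kw), fan_in, self.cout),
            "b": np.zeros(self.cout),
        }
        self.zero_grad()
        self._out = tuple(
            _same_pad(s, k, st)[0] for s, k, st in zip((d, h, w), self.kernel, self.stride)
        )
        self._pads = tuple(
            _same_pad(s, k, st)[1:] for s, k, st in zip((d, h, w), self.kernel, self.stride)
        )
        return (self.cout,) + self._out

    def forward(self, x, train=False):
        (pd0, pd1), (ph0, ph1), (pw0, pw1) = self._pads
        self._in_spatial = x.shape[2:]
        xp = np.pad(x, ((0, 0), (0, 0), (pd0, pd1), (ph0, ph1), (pw0, pw1)))
        self._xp_shape = xp.shape
        sd, sh, sw = self.stride
        win = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        self._win = win[:, :, ::sd, ::sh, ::sw]
        return np.einsum(
            "ncdhwijk,ocijk->nodhw", self._win, self.p["W"], optimize=True
        ) + self.p["b"][None, :, None, None, None]

    def backward(self, dy):
        self.g["W"] += np.einsum("ncdhwijk,nodhw->ocijk", self._win, dy, optimize=True)
        self.g["b"] += dy.sum(axis=(0, 2, 3, 4))
        sd, sh, sw = self.stride
        do, ho, wo = dy.shape[2:]
        dxp = np.zeros(self._xp_shape)
        w = self.p["W"]
        for i in range(self.kernel[0]):
            for j in range(self.kernel[1]):
                for k in range(self.kernel[2]):
                    contrib = np.einsum("nodhw,oc->ncdhw", dy, w[:, :, i, j, k], optimize=True)
                    dxp[
                        :, :,
                        i : i + sd * do : sd,
                        j : j + sh * ho : sh,
                        k : k + sw * wo : sw,
                    ] += contrib
        (pd0, _), (ph0, _), (pw0, _) = self._pads
        d, h, w_ = self._in_spatial
        return dxp[:, :, pd0 : pd0 + d, ph0 : ph0 + h, pw0 : pw0 + w_]


class Conv2D(Conv3D):
    """2-D convolution implemented as a 3-D convolution with a unit depth."""

    def __init__(self, out_channels, kernel=(3, 3), stride=(1, 1), name="conv2d"):
        super().__init__(out_channels, (1,) + tuple(kernel), (1,) + tuple(stride), name=name)

    def build(self, in_shape, rng):
        cin, h, w = in_shape
        out = super().build((cin, 1, h, w), rng)
        return (out[0],) + out[2:]

    def forward(self, x, train=False):
        y = super().forward(x[:, :, None, :, :], train=train)
        return y[:, :, 0]

    def backward(self, dy):
        dx = super().backward(dy[:, :, None, :, :])
        return dx[:, :, 0]


class MaxPool3D(Layer):
    """Ceil-mode max pooling with window == stride, right-padded with -inf."""

    def __init__(self, pool: tuple[int, int, int] = (1, 2, 2), name: str = "maxpool3d") -> None:
        super().__init__()
        self.pool = pool
        self.name = name

    def build(self, in_shape, rng):
        c, d, h, w = in_shape
        if min(d, h, w) < 1:
            raise ValueError(f"{self.name}: spatial input {in_shape} collapsed to zero")
        self._out = tuple(-(-s // p) for s, p in zip((d, h, w), self.pool))
        return (c,) + self._out

    def forward(self, x, train=False):
        n, c = x.shape[:2]
        pd, ph, pw = self.pool
        do, ho, wo = (-(-s // p) for s, p in zip(x.shape[2:], self.pool))
        pad = [(0, 0), (0, 0)] + [
            (0, o * p - s) for s, o, p in zip(x.shape[2:], (do, ho, wo), self.pool)
        ]
        xp = np.pad(x, pad, constant_values=-np.inf)
        self._in_shape = x.shape
        xr = (
            xp.reshape(n, c, do, pd, ho, ph, wo, pw)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, do, ho, wo, pd * ph * pw)
        )
        self._arg = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c = dy.shape[:2]
        pd, ph, pw = self.pool
        do, ho, wo = dy.shape[2:]
        flat = np.zeros((n, c, do, ho, wo, pd * ph * pw))
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        xp = (
            flat.reshape(n, c, do, ho, wo, pd, ph, pw)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, do * pd, ho * ph, wo * pw)
        )
        d, h, w = self._in_shape[2:]
        return xp[:, :, :d, :h, :w]


class DepthwiseSpatialConv(Layer):
    """EEGNet's depthwise spatial filter: a full-height kernel per feature map.

    Input ``(N, F, C, T)`` -> output ``(N, F * depth_mult, T)``; each of the
    F temporal feature maps gets ``depth_mult`` learned spatial filters over
    all C channels (valid padding collapses the channel axis).
    """

    def __init__(self, depth_mult: int = 2, name: str = "depthwise_spatial") -> None:
        super().__init__()
        self.depth_mult = depth_mult
        self.name = name

    def build(self, in_shape, rng):
        f, c, t = in_shape
        self.p = {"W": glorot(rng, (f, self.depth_mult, c), c, self.depth_mult)}
        self.zero_grad()
        return (f * self.depth_mult, t)

    def forward(self, x, train=False):
        self._x = x
        n, f, c, t = x.shape
        y = np.einsum("nfct,fdc->nfdt", x, self.p["W"], optimize=True)
        return y.reshape(n, f * self.depth_mult, t)

    def backward(self, dy):
        n, _, t = dy.shape
        f, d, c = self.p["W"].shape
        dy4 = dy.reshape(n, f, d, t)
        self.g["W"] += np.einsum("nfct,nfdt->fdc", self._x, dy4, optimize=True)
        return np.einsum("nfdt,fdc->nfct", dy4, self.p["W"], optimize=True)


class DepthwiseTemporalConv(Layer):
    """Per-channel convolution along time, same padding, stride 1."""

    def __init__(self, kernel: int = 16, name: str = "depthwise_temporal") -> None:
        super().__init__()
        self.kernel = kernel
        self.name = name

    def build(self, in_shape, rng):
        c, t = in_shape
        self.p = {"W": glorot(rng, (c, self.kernel), self.kernel, 1)}
        self.zero_grad()
        return in_shape

    def forward(self, x, train=False):
        k = self.kernel
        before = (k - 1) // 2
        self._before = before
        xp = np.pad(x, ((0, 0), (0, 0), (before, k - 1 - before)))
        self._win = sliding_window_view(xp, k, axis=2)
        self._t = x.shape[2]
        return np.einsum("nctk,ck->nct", self._win, self.p["W"], optimize=True)

    def backward(self, dy):
        self.g["W"] += np.einsum("nctk,nct->ck", self._win, dy, optimize=True)
        k, t = self.kernel, self._t
        dxp = np.zeros((dy.shape[0], dy.shape[1], t + k - 1))
        w = self.p["W"]
        for i in range(k):
            dxp[:, :, i : i + t] += dy * w[None, :, i, None]
        return dxp[:, :, self._before : self._before + t]


class PointwiseConv(Layer):
    """1x1 convolution mixing channels of a ``(N, C, T)`` tensor."""

    def __init__(self, out_channels: int, name: str = "pointwise") -> None:
        super().__init__()
        self.cout = out_channels
        self.name = name

    def build(self, in_shape, rng):
        c, t = in_shape
        self.p = {"W": glorot(rng, (c, self.cout), c, self.cout), "b": np.zeros(self.cout)}
        self.zero_grad()
        return (self.cout, t)

    def forward(self, x, train=False):
        self._x = x
        return np.einsum("nct,co->not", x, self.p["W"], optimize=True) + self.p["b"][None, :, None]

    def backward(self, dy):
        self.g["W"] += np.einsum("nct,not->co", self._x, dy, optimize=True)
        self.g["b"] += dy.sum(axis=(0, 2))
        return np.einsum("not,co->nct", dy, self.p["W"], optimize=True)


class AvgPoolTime(Layer):
    """Average pooling along the last (time) axis; trailing remainder dropped."""

    def __init__(self, pool: int, name: str = "avgpool") -> None:
        super().__init__()
        self.pool = pool
        self.name = name

    def build(self, in_shape, rng):
        t = in_shape[-1]
        if t < self.pool:
            raise ValueError(f"{self.name}: time axis {t} shorter than pool {self.pool}")
        return in_shape[:-1] + (t // self.pool,)

    def forward(self, x, train=False):
        self._t = x.shape[-1]
        to = self._t // self.pool
        xr = x[..., : to * self.pool].reshape(x.shape[:-1] + (to, self.pool))
        return xr.mean(axis=-1)

    def backward(self, dy):
        rep = np.repeat(dy, self.pool, axis=-1) / self.pool
        pad = self._t - rep.shape[-1]
        if pad:
            width = [(0, 0)] * (rep.ndim - 1) + [(0, pad)]
            rep = np.pad(rep, width)
        return rep
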