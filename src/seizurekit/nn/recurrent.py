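"""Recurrent layers (GRU, LSTM), bidirectional wrapping, and attention
pooling over time. Inputs are ``(N, T, F)``; gate projections of the input
are computed for all timesteps in one matmul, the recurrence loops over T.
Backward passes are full backpropagation through time."""

from __future__ import annotations

import numpy as np

from .core import Layer, glorot

__all__ = ["GRU", "LSTM", "Bidirectional", "AttentionPool", "LastStep"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class GRU(Layer):
    """Gated recurrent unit.

    Gate order in the stacked weight matrices is (update z, reset r,
    candidate h). State update: ``h = (1 - z) * h_prev + z * h_cand``.
    """

    def __init__(self, units: int, return_sequences: bool = False, name: str = "gru") -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.name = name

    def build(self, in_shape, rng):
        t, f = in_shape
        h = self.units
        self.p = {
            "W": glorot(rng, (f, 3 * h), f, h),
            "U": glorot(rng, (h, 3 * h), h, h),
            "b": np.zeros(3 * h),
        }
        self.zero_grad()
        return (t, h) if self.return_sequences else (h,)

    def forward(self, x, train=False):
        n, t, f = x.shape
        h = self.units
        xw = x @ self.p["W"] + self.p["b"]  # (N, T, 3H)
        u = self.p["U"]
        uz, ur, uh = u[:, :h], u[:, h : 2 * h], u[:, 2 * h :]
        hs = np.zeros((n, h))
        cache = []
        outs = np.empty((n, t, h))
        for step in range(t):
            az = xw[:, step, :h] + hs @ uz
            ar = xw[:, step, h : 2 * h] + hs @ ur
            z = _sigmoid(az)
            r = _sigmoid(ar)
            rh = r * hs
            ah = xw[:, step, 2 * h :] + rh @ uh
            hh = np.tanh(ah)
            h_new = (1.0 - z) * hs + z * hh
            cache.append((hs, z, r, hh, rh))
            hs = h_new
            outs[:, step] = hs
        self._cache = cache
        self._x = x
        return outs if self.return_sequences else hs

    def backward(self, dy):
        x = self._x
        n, t, f = x.shape
        h = self.units
        u = self.p["U"]
        uz, ur, uh = u[:, :h], u[:, h : 2 * h], u[:, 2 * h :]
        dW = np.zeros_like(self.p["W"])
        dU = np.zeros_like(u)
        db = np.zeros_like(self.p["b"])
        dx = np.zeros_like(x)
        dh = np.zeros((n, h))
        for step in range(t - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dy[:, step]
            elif step == t - 1:
                dh = dh + dy
            h_prev, z, r, hh, rh = self._cache[step]
            dz = dh * (hh - h_prev)
            dhh = dh * z
            dh_prev = dh * (1.0 - z)
            dah = dhh * (1.0 - hh * hh)
            drh = dah @ uh.T
            dr = drh * h_prev
            dh_prev += drh * r
            dar = dr * r * (1.0 - r)
            daz = dz * z * (1.0 - z)
            dh_prev += dar @ ur.T + daz @ uz.T
            da = np.concatenate([daz, dar, dah], axis=1)  # (N, 3H)
            xt = x[:, step]
            dW += xt.T @ da
            dU[:, :h] += h_prev.T @ daz
            dU[:, h : 2 * h] += h_prev.T @ dar
            dU[:, 2 * h :] += rh.T @ dah
            db += da.sum(axis=0)
            dx[:, step] = da @ self.p["W"].T
            dh = dh_prev
        self.g["W"] += dW
        self.g["U"] += dU
        self.g["b"] += db
        return dx


class LSTM(Layer):
    """Long short-term memory; gate order (input i, forget f, output o,
    candidate g); forget-gate bias initialised to 1."""

    def __init__(self, units: int, return_sequences: bool = False, name: str = "lstm") -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.name = name

    def build(self, in_shape, rng):
        t, f = in_shape
        h = self.units
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0
        self.p = {
            "W": glorot(rng, (f, 4 * h), f, h),
            "U": glorot(rng, (h, 4 * h), h, h),
            "b": b,
        }
        self.zero_grad()
        return (t, h) if self.return_sequences else (h,)

    def forward(self, x, train=False):
        n, t, f = x.shape
        h = self.units
        xw = x @ self.p["W"] + self.p["b"]
        u = self.p["U"]
        hs = np.zeros((n, h))
        cs = np.zeros((n, h))
        cache = []
        outs = np.empty((n, t, h))
        for step in range(t):
            a = xw[:, step] + hs @ u
            i = _sigmoid(a[:, :h])
            fgt = _sigmoid(a[:, h : 2 * h])
            o = _sigmoid(a[:, 2 * h : 3 * h])
            g = np.tanh(a[:, 3 * h :])
            c_new = fgt * cs + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((hs, cs, i, fgt, o, g, tanh_c))
            hs, cs = h_new, c_new
            outs[:, step] = hs
        self._cache = cache
        self._x = x
        return outs if self.return_sequences else hs

    def backward(self, dy):
        x = self._x
        n, t, f = x.shape
        h = self.units
        u = self.p["U"]
        dW = np.zeros_like(self.p["W"])
        dU = np.zeros_like(u)
        db = np.zeros_like(self.p["b"])
        dx = np.zeros_like(x)
        dh = np.zeros((n, h))
        dc = np.zeros((n, h))
        for step in range(t - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dy[:, step]
            elif step == t - 1:
                dh = dh + dy
            h_prev, c_prev, i, fgt, o, g, tanh_c = self._cache[step]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_prev = dc * fgt
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * fgt * (1.0 - fgt),
                    do * o * (1.0 - o),
                    dg * (1.0 - g * g),
                ],
                axis=1,
            )
            dW += x[:, step].T @ da
            dU += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, step] = da @ self.p["W"].T
            dh = da @ u.T
            dc = dc_prev
        self.g["W"] += dW
        self.g["U"] += dU
        self.g["b"] += db
        return dx


class Bidirectional(Layer):
    """Run one recurrent layer forward in time and a twin backward; concat."""

    def __init__(self, fwd: Layer, bwd: Layer, name: str = "bidirectional") -> None:
        super().__init__()
        if fwd.return_sequences != bwd.return_sequences:
            raise ValueError("both directions must agree on return_sequences")
        self.fwd = fwd
        self.bwd = bwd
        self.return_sequences = fwd.return_sequences
        self.name = name

    def build(self, in_shape, rng):
        out_f = self.fwd.build(in_shape, rng)
        self.bwd.build(in_shape, rng)
        return out_f[:-1] + (2 * out_f[-1],)

    def forward(self, x, train=False):
        yf = self.fwd.forward(x, train=train)
        yb = self.bwd.forward(x[:, ::-1], train=train)
        if self.return_sequences:
            yb = yb[:, ::-1]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dy):
        half = dy.shape[-1] // 2
        dyf, dyb = dy[..., :half], dy[..., half:]
        if self.return_sequences:
            dyb = dyb[:, ::-1]
        dxf = self.fwd.backward(np.ascontiguousarray(dyf))
        dxb = self.bwd.backward(np.ascontiguousarray(dyb))[:, ::-1]
        return dxf + dxb

    def zero_grad(self):
        self.fwd.zero_grad()
        self.bwd.zero_grad()

    @property
    def p(self):  # expose sublayer params to the optimizer / counter
        return {
            **{f"fwd_{k}": v for k, v in self.fwd.p.items()},
            **{f"bwd_{k}": v for k, v in self.bwd.p.items()},
        }

    @p.setter
    def p(self, value):
        if value:  # only the base-class empty init passes a falsy dict
            raise AttributeError("set sublayer params directly")

    @property
    def g(self):
        return {
            **{f"fwd_{k}": v for k, v in self.fwd.g.items()},
            **{f"bwd_{k}": v for k, v in self.bwd.g.items()},
        }

    @g.setter
    def g(self, value):
        if value:
            raise AttributeError("set sublayer grads directly")

    def get_state(self):
        return {"fwd": self.fwd.get_state(), "bwd": self.bwd.get_state()}

    def set_state(self, state):
        self.fwd.set_state(state["fwd"])
        self.bwd.set_state(state["bwd"])


class AttentionPool(Layer):
    """Learned softmax-over-time pooling of recurrent states.

    Scores ``s_t = v . tanh(W h_t + b)`` are softmax-normalised over time and
    the states are averaged with those weights: ``(N, T, F) -> (N, F)``.
    """

    def __init__(self, attn_units: int = 64, name: str = "attention_pool") -> None:
        super().__init__()
        self.attn_units = attn_units
        self.name = name

    def build(self, in_shape, rng):
        t, f = in_shape
        a = self.attn_units
        self.p = {
            "W": glorot(rng, (f, a), f, a),
            "b": np.zeros(a),
            "v": glorot(rng, (a,), a, 1),
        }
        self.zero_grad()
        return (f,)

    def forward(self, x, train=False):
        u = np.tanh(x @ self.p["W"] + self.p["b"])  # (N, T, A)
        s = u @ self.p["v"]  # (N, T)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        alpha = e / e.sum(axis=1, keepdims=True)
        self._x, self._u, self._alpha = x, u, alpha
        return np.einsum("nt,ntf->nf", alpha, x, optimize=True)

    def backward(self, dy):
        x, u, alpha = self._x, self._u, self._alpha
        dalpha = np.einsum("ntf,nf->nt", x, dy, optimize=True)
        dx = alpha[..., None] * dy[:, None, :]
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        du = ds[..., None] * self.p["v"]
        da = du * (1.0 - u * u)
        self.g["W"] += np.einsum("ntf,nta->fa", x, da, optimize=True)
        self.g["b"] += da.sum(axis=(0, 1))
        self.g["v"] += (u * ds[..., None]).sum(axis=(0, 1))
        dx += da @ self.p["W"].T
        return dx


class LastStep(Layer):
    """Select the final timestep of a ``(N, T, F)`` sequence."""

    def build(self, in_shape, rng):
        self._t = in_shape[0]
        return (in_shape[1],)

    def forward(self, x, train=False):
        self._shape = x.shape
        return x[:, -1]

    def backward(self, dy):
        dx = np.zeros(self._shape)
        dx[:, -1] = dy
        return dx
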