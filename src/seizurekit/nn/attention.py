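"""Layer normalization, multi-head self-attention, and a post-LN transformer
encoder block, for the convolution-plus-transformer EEG classifier."""

from __future__ import annotations

import numpy as np

from .core import Dense, Layer, ReLU, Dropout, glorot

__all__ = ["LayerNorm", "MultiHeadSelfAttention", "TransformerBlock"]


class LayerNorm(Layer):
    """Normalization over the last axis with learned scale/shift."""

    def __init__(self, eps: float = 1e-5, name: str = "layernorm") -> None:
        super().__init__()
        self.eps = eps
        self.name = name

    def build(self, in_shape, rng):
        f = in_shape[-1]
        self.p = {"gamma": np.ones(f), "beta": np.zeros(f)}
        self.zero_grad()
        return in_shape

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = xc * self._inv
        return self.p["gamma"] * self._xhat + self.p["beta"]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.g["gamma"] += (dy * self._xhat).sum(axis=axes)
        self.g["beta"] += dy.sum(axis=axes)
        dxhat = dy * self.p["gamma"]
        return self._inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=-1, keepdims=True)
        )


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention over ``(N, T, D)`` tokens."""

    def __init__(self, n_heads: int = 2, name: str = "mhsa") -> None:
        super().__init__()
        self.n_heads = n_heads
        self.name = name

    def build(self, in_shape, rng):
        t, d = in_shape
        if d % self.n_heads:
            raise ValueError(f"{self.name}: model dim {d} not divisible by {self.n_heads} heads")
        self.d = d
        self.dh = d // self.n_heads
        self.p = {
            "Wq": glorot(rng, (d, d), d, d),
            "Wk": glorot(rng, (d, d), d, d),
            "Wv": glorot(rng, (d, d), d, d),
            "Wo": glorot(rng, (d, d), d, d),
            "bo": np.zeros(d),
        }
        self.zero_grad()
        return in_shape

    def _split(self, x):
        n, t, _ = x.shape
        return x.reshape(n, t, self.n_heads, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):
        n, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * dh)

    def forward(self, x, train=False):
        self._x = x
        q = self._split(x @ self.p["Wq"])
        k = self._split(x @ self.p["Wk"])
        v = self._split(x @ self.p["Wv"])
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        ctx = attn @ v
        merged = self._merge(ctx)
        self._q, self._k, self._v, self._attn, self._merged = q, k, v, attn, merged
        return merged @ self.p["Wo"] + self.p["bo"]

    def backward(self, dy):
        x = self._x
        n, t, d = x.shape
        dy2 = dy.reshape(-1, d)
        self.g["Wo"] += self._merged.reshape(-1, d).T @ dy2
        self.g["bo"] += dy2.sum(axis=0)
        dmerged = dy @ self.p["Wo"].T
        dctx = self._split(dmerged)
        dattn = dctx @ self._v.transpose(0, 1, 3, 2)
        dv = self._attn.transpose(0, 1, 3, 2) @ dctx
        a = self._attn
        dscores = a * (dattn - (dattn * a).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.dh)
        dq = dscores @ self._k
        dk = dscores.transpose(0, 1, 3, 2) @ self._q
        dq_m, dk_m, dv_m = self._merge(dq), self._merge(dk), self._merge(dv)
        x2 = x.reshape(-1, d)
        self.g["Wq"] += x2.T @ dq_m.reshape(-1, d)
        self.g["Wk"] += x2.T @ dk_m.reshape(-1, d)
        self.g["Wv"] += x2.T @ dv_m.reshape(-1, d)
        return dq_m @ self.p["Wq"].T + dk_m @ self.p["Wk"].T + dv_m @ self.p["Wv"].T


class TransformerBlock(Layer):
    """Post-LN encoder block: self-attention and a position-wise feed-forward
    network, each wrapped in a residual connection and layer norm."""

    def __init__(self, n_heads: int = 2, ff_mult: int = 2, dropout: float = 0.1, name: str = "transformer") -> None:
        super().__init__()
        self.name = name
        self.mhsa = MultiHeadSelfAttention(n_heads, name=f"{name}.mhsa")
        self.ln1 = LayerNorm(name=f"{name}.ln1")
        self.ln2 = LayerNorm(name=f"{name}.ln2")
        self.ff_mult = ff_mult
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)
        self.relu = ReLU()

    def build(self, in_shape, rng):
        t, d = in_shape
        self.d1 = Dense(self.ff_mult * d, name=f"{self.name}.ff1")
        self.d2 = Dense(d, name=f"{self.name}.ff2")
        self.mhsa.build(in_shape, rng)
        self.drop1.build(in_shape, rng)
        self.ln1.build(in_shape, rng)
        hidden = self.d1.build(in_shape, rng)
        self.d2.build(hidden, rng)
        self.drop2.build(in_shape, rng)
        self.ln2.build(in_shape, rng)
        self._subs = [self.mhsa, self.ln1, self.d1, self.d2, self.ln2]
        return in_shape

    def forward(self, x, train=False):
        a = self.drop1.forward(self.mhsa.forward(x, train), train)
        y1 = self.ln1.forward(x + a, train)
        f = self.drop2.forward(
            self.d2.forward(self.relu.forward(self.d1.forward(y1, train), train), train),
            train,
        )
        return self.ln2.forward(y1 + f, train)

    def backward(self, dy):
        dsum2 = self.ln2.backward(dy)
        df = self.drop2.backward(dsum2)
        dy1 = dsum2 + self.d1.backward(self.relu.backward(self.d2.backward(df)))
        dsum1 = self.ln1.backward(dy1)
        da = self.drop1.backward(dsum1)
        return dsum1 + self.mhsa.backward(da)

    def zero_grad(self):
        for sub in self._subs:
            sub.zero_grad()

    @property
    def p(self):
        out = {}
        for i, sub in enumerate(getattr(self, "_subs", [])):
            for k, v in sub.p.items():
                out[f"s{i}_{k}"] = v
        return out

    @p.setter
    def p(self, value):
        if value:
            raise AttributeError("set sublayer params directly")

    @property
    def g(self):
        out = {}
        for i, sub in enumerate(getattr(self, "_subs", [])):
            for k, v in sub.g.items():
                out[f"s{i}_{k}"] = v
        return out

    @g.setter
    def g(self, value):
        if value:
            raise AttributeError("set sublayer grads directly")

    def get_state(self):
        return {"subs": [sub.get_state() for sub in self._subs]}

    def set_state(self, state):
        for sub, s in zip(self._subs, state["subs"]):
            sub.set_state(s)
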