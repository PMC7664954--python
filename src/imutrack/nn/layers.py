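"""Layers with explicit forward/backward passes on (batch, time, features)
arrays.  Gradients accumulate into ``layer.grads`` until ``zero_grad``."""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "Layer", "Dense", "Dropout", "LSTM"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, g in self.grads.items():
            g[...] = 0.0

    def _register(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)


class Dense(Layer):
    """Affine map applied to the trailing feature dimension."""

    def __init__(self, in_size: int, out_size: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (in_size + out_size))
        self._register("W", rng.uniform(-limit, limit, size=(in_size, out_size)))
        self._register("b", np.zeros(out_size))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.grads["W"] += np.tensordot(x, dy, axes=(tuple(range(x.ndim - 1)),) * 2)
        self.grads["b"] += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity when not training or rate == 0."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        assert rng is not None, "training-mode dropout needs an rng"
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class LSTM(Layer):
    """Single LSTM layer over (B, T, D) input, returning all hidden states.

    Gate order in the packed weight matrices is (i, f, g, o).  With
    ``cell_activation="linear"`` the candidate activation is the identity
    and the hidden state is ``o * c`` (no output squashing) — the form the
    integrative initialization relies on.  ``recurrent_dropout`` applies a
    per-sequence (variational) mask to the recurrent hidden input.
    """

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        rng: np.random.Generator,
        cell_activation: str = "tanh",
        recurrent_dropout: float = 0.0,
        forget_bias: float = 1.0,
    ):
        super().__init__()
        if cell_activation not in ("tanh", "linear"):
            raise ValueError(f"unknown cell activation {cell_activation!r}")
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.cell_activation = cell_activation
        self.recurrent_dropout = recurrent_dropout

        H, D = hidden_size, input_size
        limit = np.sqrt(6.0 / (D + H))
        self._register("Wx", rng.uniform(-limit, limit, size=(D, 4 * H)))
        Wh = np.concatenate(
            [np.linalg.qr(rng.standard_normal((H, H)))[0] for _ in range(4)], axis=1
        )
        self._register("Wh", Wh)
        b = np.zeros(4 * H)
        b[H : 2 * H] = forget_bias
        self._register("b", b)
        self._cache: dict | None = None

    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        B, T, D = x.shape
        H = self.hidden_size
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        linear = self.cell_activation == "linear"

        rmask = None
        if training and self.recurrent_dropout > 0:
            assert rng is not None, "recurrent dropout needs an rng"
            rmask = (rng.random((B, H)) >= self.recurrent_dropout) / (
                1.0 - self.recurrent_dropout
            )

        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache = {"x": x, "i": [], "f": [], "g": [], "o": [], "c": [], "hprev": [],
                 "cprev": [], "zg": [], "rmask": rmask}
        for t in range(T):
            hdrop = h * rmask if rmask is not None else h
            z = x[:, t] @ Wx + hdrop @ Wh + b
            zi, zf, zg, zo = np.split(z, 4, axis=1)
            i = sigmoid(zi)
            f = sigmoid(zf)
            g = zg if linear else np.tanh(zg)
            o = sigmoid(zo)
            c_new = f * c + i * g
            h_new = o * (c_new if linear else np.tanh(c_new))
            cache["hprev"].append(hdrop)
            cache["cprev"].append(c)
            cache["i"].append(i)
            cache["f"].append(f)
            cache["g"].append(g)
            cache["o"].append(o)
            cache["zg"].append(zg)
            cache["c"].append(c_new)
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = cache
        return hs

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        cache = self._cache
        assert cache is not None, "forward must run before backward"
        x = cache["x"]
        B, T, D = x.shape
        H = self.hidden_size
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        linear = self.cell_activation == "linear"
        rmask = cache["rmask"]

        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            dh = dh_out[:, t] + dh_next
            i, f, g, o = (cache[k][t] for k in ("i", "f", "g", "o"))
            c = cache["c"][t]
            c_prev = cache["cprev"][t]
            if linear:
                do = dh * c
                dc = dh * o + dc_next
            else:
                tc = np.tanh(c)
                do = dh * tc
                dc = dh * o * (1 - tc**2) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dzg = dg if linear else dg * (1 - g**2)
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dzg, do * o * (1 - o)], axis=1
            )
            dWx += x[:, t].T @ dz
            dWh += cache["hprev"][t].T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
            if rmask is not None:
                dh_next = dh_next * rmask
            dc_next = dc * f
        self.grads["Wx"] += dWx
        self.grads["Wh"] += dWh
        self.grads["b"] += db
        return dx
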