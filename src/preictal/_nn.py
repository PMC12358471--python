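"""Minimal seeded neural-network backend (numpy forward/backward + Adam).

Implements exactly the layer set the 1-D CNN architecture needs — valid
stride-1 convolution, batch normalization, leaky ReLU, max/average pooling,
dropout, global average pooling, dense — plus a single-timestep LSTM cell
used as one of the ensemble's base classifiers.  Everything is plain
float32 numpy with hand-written gradients and an Adam update; all
randomness (init, shuffling, dropout) flows from one integer seed, so
identical (data, config, seed) reproduces identical parameters bit for bit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F = np.float32


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F)


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padded stride-1 cross-correlation, x: (B, C, L) -> (B, O, L-k+1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.params = {
            "W": _he_init(rng, (out_ch, in_ch, kernel), in_ch * kernel),
            "b": np.zeros(out_ch, dtype=F),
        }

    def forward(self, x, train):
        self._xw = sliding_window_view(x, self.kernel, axis=2)  # (B,C,Lo,k)
        out = np.einsum("ock,bclk->bol", self.params["W"], self._xw, optimize=True)
        return out + self.params["b"][None, :, None]

    def backward(self, g):
        self.grads["W"] = np.einsum("bol,bclk->ock", g, self._xw, optimize=True)
        self.grads["b"] = g.sum(axis=(0, 2))
        k = self.kernel
        gp = np.pad(g, ((0, 0), (0, 0), (k - 1, k - 1)))
        wf = self.params["W"][:, :, ::-1]
        gw = sliding_window_view(gp, k, axis=2)  # (B,O,Li,k)
        return np.einsum("ock,bolk->bcl", wf, gw, optimize=True)


class BatchNorm1D(Layer):
    """Per-channel normalization over (batch, time); 4 parameters/channel
    (scale, shift + running mean/variance used at inference)."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(n_ch, dtype=F), "beta": np.zeros(n_ch, dtype=F)}
        self.running_mean = np.zeros(n_ch, dtype=F)
        self.running_var = np.ones(n_ch, dtype=F)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None]
        self._xhat = (x - mean[None, :, None]) / self._std
        return self.params["gamma"][None, :, None] * self._xhat + self.params["beta"][None, :, None]

    def backward(self, g):
        self.grads["gamma"] = (g * self._xhat).sum(axis=(0, 2))
        self.grads["beta"] = g.sum(axis=(0, 2))
        n = g.shape[0] * g.shape[2]
        gx_hat = g * self.params["gamma"][None, :, None]
        term = (
            gx_hat
            - gx_hat.mean(axis=(0, 2), keepdims=True)
            - self._xhat * (gx_hat * self._xhat).mean(axis=(0, 2), keepdims=True)
        )
        del n
        return term / self._std


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        p = self.pool
        self._in_len = x.shape[2]
        lo = x.shape[2] // p
        xr = x[:, :, : lo * p].reshape(x.shape[0], x.shape[1], lo, p)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, g):
        p = self.pool
        b, c, lo = g.shape
        out = np.zeros((b, c, self._in_len), dtype=g.dtype)
        bi, ci, li = np.ogrid[:b, :c, :lo]
        out.reshape(b, c, -1)[..., : lo * p].reshape(b, c, lo, p)[
            bi, ci, li, self._argmax
        ] = g
        return out


class AvgPool1D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        p = self.pool
        self._in_len = x.shape[2]
        lo = x.shape[2] // p
        return x[:, :, : lo * p].reshape(x.shape[0], x.shape[1], lo, p).mean(axis=3)

    def backward(self, g):
        p = self.pool
        b, c, lo = g.shape
        out = np.zeros((b, c, self._in_len), dtype=g.dtype)
        out[:, :, : lo * p] = np.repeat(g / p, p, axis=2)
        return out


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep).astype(F) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class GlobalAvgPool1D(Layer):
    def forward(self, x, train):
        self._in_len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g):
        return np.repeat(g[:, :, None], self._in_len, axis=2) / self._in_len


class Dense(Layer):
    """Linear layer on (B, F_in) -> (B, F_out)."""

    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": _he_init(rng, (out_f, in_f), in_f),
            "b": np.zeros(out_f, dtype=F),
        }

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, g):
        self.grads["W"] = g.T @ self._x
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60))),
                    np.exp(np.clip(z, -60, 60)) / (1.0 + np.exp(np.clip(z, -60, 60))))


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


class Adam:
    """Adaptive-moment optimizer over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k].astype(F)
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / (1 - self.b1**self.t)
                vhat = self.v[i][k] / (1 - self.b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F)


class LSTMClassifier:
    """Single-timestep LSTM cell + sigmoid readout for static vectors.

    Each input vector is treated as a length-1 sequence: the cell consumes
    it once from zero initial state, and the final hidden state feeds a
    one-unit dense sigmoid output.  Trained with binary cross-entropy and
    Adam; fully deterministic given the seed.
    """

    def __init__(self, n_units: int = 32, epochs: int = 80, batch_size: int = 32,
                 learning_rate: float = 1e-2, seed: int = 0):
        self.n_units = n_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        x = np.asarray(x, dtype=F)
        y = np.asarray(y, dtype=F).ravel()
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        rng = np.random.default_rng(self.seed)
        d, h = x.shape[1], self.n_units
        self.Wx = _he_init(rng, (4 * h, d), d)
        self.b = np.zeros(4 * h, dtype=F)
        # forget-gate bias is conventionally 1; with a single step it only
        # shifts the (unused) forget gate, kept for familiarity
        self.b[h : 2 * h] = 1.0
        self.Wo = _he_init(rng, (h,), h)
        self.bo = np.zeros(1, dtype=F)

        params = [self.Wx, self.b, self.Wo, self.bo]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0
        n = x.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for i0 in range(0, n, self.batch_size):
                idx = order[i0 : i0 + self.batch_size]
                xb, yb = x[idx], y[idx]
                p, cache = self._forward(xb)
                grads = self._backward(p, yb, cache)
                t += 1
                for j, (pp, g) in enumerate(zip(params, grads)):
                    m[j] = 0.9 * m[j] + 0.1 * g
                    v[j] = 0.999 * v[j] + 0.001 * g * g
                    mhat = m[j] / (1 - 0.9**t)
                    vhat = v[j] / (1 - 0.999**t)
                    pp -= (self.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)).astype(F)
        return self

    def _forward(self, x):
        h = self.n_units
        z = x @ self.Wx.T + self.b
        i = sigmoid(z[:, :h])
        f = sigmoid(z[:, h : 2 * h])
        g = np.tanh(z[:, 2 * h : 3 * h])
        o = sigmoid(z[:, 3 * h :])
        c = i * g  # zero initial cell state; f multiplies c0 = 0
        tc = np.tanh(c)
        hvec = o * tc
        logit = hvec @ self.Wo + self.bo
        p = sigmoid(logit)
        return p, (x, i, f, g, o, c, tc, hvec)

    def _backward(self, p, y, cache):
        x, i, f, g, o, c, tc, hvec = cache
        b = x.shape[0]
        dlogit = (p - y) / b
        gWo = hvec.T @ dlogit
        gbo = np.array([dlogit.sum()], dtype=F)
        dh = dlogit[:, None] * self.Wo[None, :]
        do = dh * tc
        dc = dh * o * (1 - tc**2)
        di = dc * g
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), np.zeros_like(f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        gWx = dz.T @ x
        gb = dz.sum(axis=0)
        return [gWx.astype(F), gb.astype(F), gWo.astype(F), gbo]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p, _ = self._forward(np.asarray(x, dtype=F))
        return p

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x) >= 0.5).astype(int)
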