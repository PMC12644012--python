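"""Compact NumPy neural-network layers with explicit backprop.

Everything runs in float64 on small problems (feature vectors of a few
hundred dimensions, batches of 32), so clarity and exact reproducibility
win over speed. Layers follow a uniform micro-protocol:

* ``forward(x, training=...)`` caches what backward needs,
* ``backward(dy)`` returns dx and accumulates parameter gradients,
* ``params`` / ``grads`` are dicts of arrays sharing the layer's storage.

Gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d", "BatchNorm1d", "ReLU", "Dropout", "Dense", "GRU",
    "Adam", "softmax", "softmax_cross_entropy",
]


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d:
    """1-D convolution with same-padding (odd kernel), input (N, C_in, D)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd for same-padding")
        self.k = kernel
        fan_in = c_in * kernel
        self.params = {
            "W": _uniform_init(rng, (c_out, c_in, kernel), fan_in),
            "b": _uniform_init(rng, (c_out,), fan_in),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, p = self.k, (self.k - 1) // 2
        n, c, d = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p)))
        col = np.stack([xpad[:, :, i:i + d] for i in range(k)], axis=2)  # (N,C,k,D)
        y = np.einsum("oik,nikd->nod", self.params["W"], col)
        y += self.params["b"][None, :, None]
        self._cache = (col, d)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, d = self._cache
        k, p = self.k, (self.k - 1) // 2
        self.grads["W"] += np.einsum("nod,nikd->oik", dy, col)
        self.grads["b"] += dy.sum(axis=(0, 2))
        dcol = np.einsum("oik,nod->nikd", self.params["W"], dy)
        n, c = col.shape[0], col.shape[1]
        dxpad = np.zeros((n, c, d + 2 * p))
        for i in range(k):
            dxpad[:, :, i:i + d] += dcol[:, :, i, :]
        return dxpad[:, :, p:p + d] if p else dxpad


class BatchNorm1d:
    """Per-channel batch normalization over (N, C, D); running stats for eval."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        g = self.params["gamma"][None, :, None]
        b = self.params["beta"][None, :, None]
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv[None, :, None]
        self._cache = (x, xhat, mu, inv, training)
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, xhat, mu, inv, training = self._cache
        g = self.params["gamma"]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] += dy.sum(axis=(0, 2))
        dxhat = dy * g[None, :, None]
        if not training:
            return dxhat * inv[None, :, None]
        n, _, d = x.shape
        m = n * d
        xc = x - mu[None, :, None]
        dvar = (dxhat * xc).sum(axis=(0, 2)) * (-0.5) * inv ** 3
        dmu = -(dxhat.sum(axis=(0, 2)) * inv) - 2.0 * dvar * xc.mean(axis=(0, 2))
        return (dxhat * inv[None, :, None]
                + (2.0 / m) * dvar[None, :, None] * xc
                + dmu[None, :, None] / m)


class ReLU:
    params: dict = {}
    grads: dict = {}

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout:
    """Inverted dropout; identity in eval mode. Needs an rng during training."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, p: float):
        if not (0 <= p < 1):
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        self._mask = (rng.uniform(size=x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.params = {
            "W": _uniform_init(rng, (n_in, n_out), n_in),
            "b": _uniform_init(rng, (n_out,), n_in),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GRU:
    """Gated recurrent unit over (N, T, I); returns the final hidden state.

    Gates: z = sig(x Wz + h Uz + bz), r = sig(x Wr + h Ur + br),
    c = tanh(x Wc + r * (h Uc) + bc), h' = (1 - z) * c + z * h.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        p = {}
        for g in ("z", "r", "c"):
            p[f"W{g}"] = _uniform_init(rng, (n_in, hidden), hidden)
            p[f"U{g}"] = _uniform_init(rng, (hidden, hidden), hidden)
            p[f"b{g}"] = _uniform_init(rng, (hidden,), hidden)
        self.params = p
        self.grads = {k: np.zeros_like(v) for k, v in p.items()}
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t, _ = x.shape
        p = self.params
        h = np.zeros((n, self.hidden))
        steps = []
        for i in range(t):
            xt = x[:, i, :]
            z = _sigmoid(xt @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(xt @ p["Wr"] + h @ p["Ur"] + p["br"])
            a = h @ p["Uc"]
            c = np.tanh(xt @ p["Wc"] + r * a + p["bc"])
            h_new = (1 - z) * c + z * h
            steps.append((xt, h, z, r, a, c))
            h = h_new
        self._cache = (steps, x.shape)
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        steps, (n, t, n_in) = self._cache
        p, g = self.params, self.grads
        dx = np.zeros((n, t, n_in))
        for i in range(t - 1, -1, -1):
            xt, h_prev, z, r, a, c = steps[i]
            dz_pre = dh * (h_prev - c) * z * (1 - z)
            dc_pre = dh * (1 - z) * (1 - c ** 2)
            dh_prev = dh * z
            # candidate path
            g["Wc"] += xt.T @ dc_pre
            g["bc"] += dc_pre.sum(axis=0)
            da = dc_pre * r
            g["Uc"] += h_prev.T @ da
            dh_prev = dh_prev + da @ p["Uc"].T
            dr_pre = dc_pre * a * r * (1 - r)
            # gates
            g["Wz"] += xt.T @ dz_pre
            g["Uz"] += h_prev.T @ dz_pre
            g["bz"] += dz_pre.sum(axis=0)
            dh_prev = dh_prev + dz_pre @ p["Uz"].T
            g["Wr"] += xt.T @ dr_pre
            g["Ur"] += h_prev.T @ dr_pre
            g["br"] += dr_pre.sum(axis=0)
            dh_prev = dh_prev + dr_pre @ p["Ur"].T
            dx[:, i, :] = dc_pre @ p["Wc"].T + dz_pre @ p["Wz"].T + dr_pre @ p["Wr"].T
            dh = dh_prev
        return dx


class Adam:
    """Adam over a dict of named parameter arrays (updated in place)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            gr = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gr ** 2
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-300, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n
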