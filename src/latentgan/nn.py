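"""A small NumPy neural-network core with hand-written backward passes.

Implements exactly the layers the package's two models need — dense, LSTM,
batch normalization, gaussian noise, leaky ReLU, masked softmax cross entropy
— plus Adam with global-norm gradient clipping. Everything is float64 and
seeded, so training runs are bit-reproducible and every backward pass can be
validated against central finite differences (see the test suite).

Layers store parameters and gradients as attributes and expose them through
``parameters()`` as ``(name, value, grad)`` triples; an :class:`Adam`
optimizer updates them in place.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Layer:
    """Base class: parameter bookkeeping shared by all layers."""

    _param_names: tuple[str, ...] = ()

    def parameters(self):
        for name in self._param_names:
            yield name, getattr(self, name), getattr(self, "d" + name)

    def zero_grad(self) -> None:
        for name in self._param_names:
            getattr(self, "d" + name)[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name).copy() for name in self._param_names}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name in self._param_names:
            arr = getattr(self, name)
            arr[...] = state[name]


class Dense(Layer):
    """Affine map y = x @ W + b."""

    _param_names = ("W", "b")

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = glorot(rng, d_in, d_out)
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class GaussianNoise(Layer):
    """Additive zero-centered gaussian noise, active only in training mode."""

    def __init__(self, sd: float, rng: np.random.Generator):
        self.sd = sd
        self.rng = rng
        self.active = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.active and self.sd > 0:
            return x + self.rng.normal(0.0, self.sd, size=x.shape)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy


class BatchNorm(Layer):
    """Feature-wise batch normalization over a (B, F) batch.

    ``momentum`` follows the running-average convention
    running = momentum * running + (1 - momentum) * batch.
    Evaluation mode uses the running statistics, so inference is a pure
    function of the input.
    """

    _param_names = ("gamma", "beta")

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.training = True
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, x.shape[0])
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, B = self._cache
        self.dgamma += (dy * xhat).sum(axis=0)
        self.dbeta += dy.sum(axis=0)
        if not self.training:
            return dy * self.gamma * inv_std
        dxhat = dy * self.gamma
        return inv_std / B * (
            B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    def state_dict(self):
        d = super().state_dict()
        d["running_mean"] = self.running_mean.copy()
        d["running_var"] = self.running_var.copy()
        return d

    def load_state_dict(self, state):
        super().load_state_dict(state)
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class LSTM(Layer):
    """Single unidirectional LSTM layer unrolled over full (B, T, D) batches.

    Gate order in the packed weight matrices is (input, forget, cell, output);
    the forget-gate bias is initialized to 1. ``forward`` returns the hidden
    sequence; ``backward`` consumes the gradient of that sequence (plus
    optional gradients on the final states) and returns the input-sequence
    gradient along with gradients w.r.t. the initial states, which the
    decoder's latent-to-state expansion needs.
    """

    _param_names = ("Wx", "Wh", "b")

    def __init__(self, d_in: int, n_units: int, rng: np.random.Generator):
        H = n_units
        self.n_units = H
        self.Wx = glorot(rng, d_in, 4 * H)
        self.Wh = glorot(rng, H, 4 * H)
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(
        self,
        x: np.ndarray,
        h0: np.ndarray | None = None,
        c0: np.ndarray | None = None,
    ) -> np.ndarray:
        B, T, _ = x.shape
        H = self.n_units
        h = np.zeros((B, H)) if h0 is None else h0
        c = np.zeros((B, H)) if c0 is None else c0
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            a = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev = c
            c = f * c + i * g
            tanh_c = np.tanh(c)
            h_prev_cache = h
            h = o * tanh_c
            hs[:, t] = h
            cache.append((i, f, g, o, c_prev, tanh_c, h_prev_cache))
        self._cache = (x, cache)
        return hs

    def backward(
        self,
        dhs: np.ndarray,
        dh_last: np.ndarray | None = None,
        dc_last: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x, cache = self._cache
        B, T, _ = x.shape
        H = self.n_units
        dx = np.zeros_like(x)
        dh = np.zeros((B, H)) if dh_last is None else dh_last.copy()
        dc = np.zeros((B, H)) if dc_last is None else dc_last.copy()
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tanh_c, h_prev = cache[t]
            dh = dh + dhs[:, t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f
            da = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.dWx += x[:, t].T @ da
            self.dWh += h_prev.T @ da
            self.db += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            dh = da @ self.Wh.T
        return dx, dh, dc


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def masked_softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean token-level cross entropy over masked positions.

    ``logits`` (B, T, V); ``targets`` (B, T) integer indices; ``mask`` (B, T)
    booleans selecting the positions that count. Returns (loss, dlogits).
    """
    p = softmax(logits)
    n = max(int(mask.sum()), 1)
    B, T, V = logits.shape
    idx = (np.arange(B)[:, None], np.arange(T)[None, :], targets)
    logp = np.log(np.clip(p[idx], 1e-300, None))
    loss = -(logp * mask).sum() / n
    dlogits = p.copy()
    dlogits[idx] -= 1.0
    dlogits *= (mask / n)[..., None]
    return float(loss), dlogits


def global_norm_clip(layers, max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = 0.0
    for layer in layers:
        for _, _, g in layer.parameters():
            total += float((g**2).sum())
    norm = np.sqrt(total)
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for layer in layers:
            for _, _, g in layer.parameters():
                g *= scale
    return norm


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = list(layers)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for li, layer in enumerate(self.layers):
            for name, value, grad in layer.parameters():
                key = (li, name)
                m = self._m.setdefault(key, np.zeros_like(value))
                v = self._v.setdefault(key, np.zeros_like(value))
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad**2
                value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()
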