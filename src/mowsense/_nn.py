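"""Minimal 1-D convolutional network engine (numpy, CPU).

Implements exactly what the mowing detector needs: same-padding 1-D
convolutions, a per-timestep channel softmax, batch normalization with
running inference statistics, a sigmoid head trained with binary
cross-entropy, and the Nadam optimizer (Adam with Nesterov momentum and
the classic keras momentum schedule).  Shapes follow the (batch,
channels, time) convention throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv1D", "ChannelSoftmax", "Activation", "BatchNorm", "Sequential",
           "bce_with_logits", "make_optimizer"]


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Same-length 1-D convolution, (N, C_in, T) -> (N, C_out, T)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"kernel size must be odd for same padding, got {kernel}")
        self.k = kernel
        self.pad = kernel // 2
        limit = np.sqrt(6.0 / (c_in * kernel + c_out * kernel))  # Glorot uniform
        self.params = {
            "W": rng.uniform(-limit, limit, size=(c_out, c_in, kernel)),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train):
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._patches = sliding_window_view(xp, self.k, axis=2)  # (N, C_in, T, k)
        return np.einsum("nctk,ock->not", self._patches, self.params["W"],
                         optimize=True) + self.params["b"][None, :, None]

    def backward(self, dy):
        W = self.params["W"]
        self.grads = {
            "W": np.einsum("not,nctk->ock", dy, self._patches, optimize=True),
            "b": dy.sum(axis=(0, 2)),
        }
        n, _, t = dy.shape
        c_in = W.shape[1]
        dxp = np.zeros((n, c_in, t + 2 * self.pad))
        for j in range(self.k):
            dxp[:, :, j : j + t] += np.einsum("not,ocj->nct", dy, W[:, :, j : j + 1],
                                              optimize=True)
        return dxp[:, :, self.pad : self.pad + t]


class ChannelSoftmax(Layer):
    """Softmax across the channel axis, independently at every timestep."""

    def forward(self, x, train):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=1, keepdims=True)
        return self._y

    def backward(self, dy):
        y = self._y
        return y * (dy - (dy * y).sum(axis=1, keepdims=True))


class Activation(Layer):
    """Elementwise relu / sigmoid / tanh / linear."""

    def __init__(self, kind: str):
        super().__init__()
        if kind not in ("relu", "sigmoid", "tanh", "linear"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, train):
        if self.kind == "relu":
            self._y = np.maximum(x, 0.0)
        elif self.kind == "sigmoid":
            self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        elif self.kind == "tanh":
            self._y = np.tanh(x)
        else:
            self._y = x
        return self._y

    def backward(self, dy):
        if self.kind == "relu":
            return dy * (self._y > 0)
        if self.kind == "sigmoid":
            return dy * self._y * (1.0 - self._y)
        if self.kind == "tanh":
            return dy * (1.0 - self._y ** 2)
        return dy


class BatchNorm(Layer):
    """Per-channel normalization over (batch, time); running stats at inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)[None, :, None]
            self._xhat = (x - mean[None, :, None]) / self._std
            self._m = x.shape[0] * x.shape[2]
            return self.params["gamma"][None, :, None] * self._xhat + \
                self.params["beta"][None, :, None]
        xhat = (x - self.running_mean[None, :, None]) / \
            np.sqrt(self.running_var + self.eps)[None, :, None]
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, dy):
        xhat, std, m = self._xhat, self._std, self._m
        self.grads = {
            "gamma": (dy * xhat).sum(axis=(0, 2)),
            "beta": dy.sum(axis=(0, 2)),
        }
        dxhat = dy * self.params["gamma"][None, :, None]
        return (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)) / std


class Sequential:
    """A straight stack of layers with a flat parameter view for optimizers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[np.ndarray]:
        return [layer.params[k] for layer in self.layers for k in sorted(layer.params)]

    def gradients(self) -> list[np.ndarray]:
        return [layer.grads[k] for layer in self.layers for k in sorted(layer.params)]

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state):
            p[...] = s
        extra = iter(state[len(params):])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(extra).copy()
                layer.running_var = next(extra).copy()


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over every element; returns (loss, dlogits)."""
    z, y = logits, targets
    loss = np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    return float(loss.mean()), (p - y) / y.size


class _Optimizer:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr

    def step(self, grads: list[np.ndarray]) -> None:
        raise NotImplementedError


class SGD(_Optimizer):
    def step(self, grads):
        for p, g in zip(self.params, grads):
            p -= self.lr * g


class Adam(_Optimizer):
    def __init__(self, params, lr, beta_1=0.9, beta_2=0.999, eps=1e-7):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = beta_1, beta_2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Nadam(_Optimizer):
    """Adam with Nesterov momentum and the keras-legacy momentum schedule."""

    def __init__(self, params, lr, beta_1=0.9, beta_2=0.999, eps=1e-7,
                 schedule_decay=0.004):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = beta_1, beta_2, eps
        self.sd = schedule_decay
        self.t = 0
        self.m_schedule = 1.0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads):
        self.t += 1
        t = self.t
        mu_t = self.b1 * (1.0 - 0.5 * 0.96 ** (t * self.sd))
        mu_tp1 = self.b1 * (1.0 - 0.5 * 0.96 ** ((t + 1) * self.sd))
        m_sched_new = self.m_schedule * mu_t
        m_sched_next = m_sched_new * mu_tp1
        self.m_schedule = m_sched_new
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g_prime = g / (1.0 - m_sched_new)
            m[...] = self.b1 * m + (1 - self.b1) * g
            m_prime = m / (1.0 - m_sched_next)
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            v_prime = v / (1.0 - self.b2 ** t)
            m_bar = (1.0 - mu_t) * g_prime + mu_tp1 * m_prime
            p -= self.lr * m_bar / (np.sqrt(v_prime) + self.eps)


_OPTIMIZERS = {"sgd": SGD, "adam": Adam, "nadam": Nadam}


def make_optimizer(name: str, params: list[np.ndarray], lr: float, **kwargs) -> _Optimizer:
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}")
    return cls(params, lr, **kwargs)
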