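"""Minimal numpy building blocks for 1D convolutional networks.

Layers implement ``forward(x, train)`` / ``backward(dy)`` and expose
their parameters and gradients for the optimizer.  Shapes follow the
(N, C, L) convention: batch, channels, temporal length.  Everything is
plain float64 numpy, so a fixed RNG seed gives bitwise-reproducible
training on a given machine.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base class; stateless layers only override forward/backward."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """kernel-3-style 1D convolution, stride 1, 'valid' or 'same' padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        padding: str,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"padding must be 'valid' or 'same', got {padding!r}")
        self.kernel = kernel
        self.padding = padding
        # He initialisation for ReLU nets
        std = np.sqrt(2.0 / (in_channels * kernel))
        self.W = rng.normal(0.0, std, size=(out_channels, in_channels, kernel))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        self._win: np.ndarray | None = None

    def out_length(self, length: int) -> int:
        if self.padding == "same":
            return length
        return length - self.kernel + 1

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.padding == "same":
            pad = (self.kernel - 1) // 2
            x = np.pad(x, ((0, 0), (0, 0), (pad, self.kernel - 1 - pad)))
        win = sliding_window_view(x, self.kernel, axis=2)  # (N, Cin, Lout, K)
        if train:
            self._win = win
        y = np.einsum("nclk,ock->nol", win, self.W, optimize=True)
        y += self.b[:, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win = self._win
        assert win is not None, "backward before forward"
        self.dW[...] = np.einsum("nclk,nol->ock", win, dy, optimize=True)
        self.db[...] = dy.sum(axis=(0, 2))
        K = self.kernel
        dyp = np.pad(dy, ((0, 0), (0, 0), (K - 1, K - 1)))
        dyw = sliding_window_view(dyp, K, axis=2)  # (N, Cout, Lin_padded, K)
        dx = np.einsum("nolk,ock->ncl", dyw, self.W[:, :, ::-1], optimize=True)
        if self.padding == "same":
            pad = (K - 1) // 2
            dx = dx[:, :, pad : dx.shape[2] - (K - 1 - pad)]
        self._win = None
        return dx


class BatchNorm1d(Layer):
    """Batch normalisation over (batch, time) per channel."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.params = [self.gamma, self.beta]
        self.grads = [self.dgamma, self.dbeta]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * ivar[:, None]
        if train:
            self._cache = (xhat, ivar, x.shape[0] * x.shape[2])
        return self.gamma[:, None] * xhat + self.beta[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, m = self._cache  # type: ignore[misc]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2))
        self.dbeta[...] = dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[:, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / m
        ) * ivar[:, None]
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing odd sample is dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def out_length(self, length: int) -> int:
        return length // self.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        lo = length // self.size
        xr = x[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        idx = xr.argmax(axis=-1)
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, lo = dy.shape
        dx = np.zeros(self._in_shape)
        dxr = dx[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return dx


class GlobalAvgPool1d(Layer):
    """Average each channel over time: (N, C, L) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._length, axis=2) / self._length


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, std, size=(out_features, in_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [
            (p, g)
            for layer in self.layers
            for p, g in zip(layer.params, layer.grads)
        ]


class Adam:
    """Adam optimiser updating parameters in place."""

    def __init__(
        self,
        params_and_grads: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.pg = params_and_grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pg]
        self.v = [np.zeros_like(p) for p, _ in self.pg]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for (p, g), m, v in zip(self.pg, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-300, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    return float(loss), dlogits
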