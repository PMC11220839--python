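"""Volumetric layers with explicit backpropagation.

Activations are ``(N, D, H, W, C)`` float32 arrays.  Each layer exposes
``params`` and ``grads`` dicts keyed by parameter name; ``forward`` caches
whatever ``backward`` needs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv3d", "ConvTranspose3d", "BatchNorm", "ReLU",
           "MaxPool3d", "softmax", "softmax_cross_entropy"]


class Layer:
    """Base class: parameter-free identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)).astype(np.float32)


class Conv3d(Layer):
    """3-d convolution with dimension-preserving (same) zero padding.

    Weights are ``(k, k, k, c_in, c_out)``; the forward pass accumulates one
    matrix product per kernel offset.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.pad = k, k // 2
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": _he_normal(rng, (k, k, k, c_in, c_out), fan_in=c_in * k**3),
            "b": np.zeros(c_out, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p, k = self.pad, self.k
        N, D, H, W_, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x
        out = np.zeros((N, D, H, W_, self.c_out), dtype=np.float32)
        Wk = self.params["W"]
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    xs = xp[:, a:a + D, b:b + H, c:c + W_, :]
                    out += np.matmul(xs, Wk[a, b, c])
        out += self.params["b"]
        self._cache = xp if training else None
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._cache
        p, k = self.pad, self.k
        N, D, H, W_, _ = dy.shape
        Wk = self.params["W"]
        dW = np.zeros_like(Wk)
        dxp = np.zeros_like(xp)
        dmat = dy.reshape(-1, self.c_out)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    xs = xp[:, a:a + D, b:b + H, c:c + W_, :]
                    dW[a, b, c] = xs.reshape(-1, self.c_in).T @ dmat
                    dxp[:, a:a + D, b:b + H, c:c + W_, :] += np.matmul(dy, Wk[a, b, c].T)
        self.grads = {"W": dW, "b": dy.sum(axis=(0, 1, 2, 3))}
        self._cache = None
        return dxp[:, p:p + D, p:p + H, p:p + W_, :] if p else dxp


class ConvTranspose3d(Layer):
    """Transposed 3-d convolution, kernel 3, stride 2, doubling each spatial dim."""

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if k != 3:
            raise ValueError("only kernel 3 is supported")
        rng = rng or np.random.default_rng(0)
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": _he_normal(rng, (k, k, k, c_in, c_out), fan_in=c_in * k**3),
            "b": np.zeros(c_out, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k = self.k
        N, D, H, W_, _ = x.shape
        full = np.zeros((N, 2 * D + 1, 2 * H + 1, 2 * W_ + 1, self.c_out), dtype=np.float32)
        Wk = self.params["W"]
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    full[:, a:a + 2 * D:2, b:b + 2 * H:2, c:c + 2 * W_:2, :] += \
                        np.matmul(x, Wk[a, b, c])
        out = full[:, 1:1 + 2 * D, 1:1 + 2 * H, 1:1 + 2 * W_, :] + self.params["b"]
        self._cache = (x, (D, H, W_)) if training else None
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, (D, H, W_) = self._cache
        k = self.k
        N = dy.shape[0]
        dfull = np.zeros((N, 2 * D + 1, 2 * H + 1, 2 * W_ + 1, self.c_out), dtype=np.float32)
        dfull[:, 1:1 + 2 * D, 1:1 + 2 * H, 1:1 + 2 * W_, :] = dy
        Wk = self.params["W"]
        dW = np.zeros_like(Wk)
        dx = np.zeros_like(x)
        xmat = x.reshape(-1, self.c_in)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    ds = np.ascontiguousarray(
                        dfull[:, a:a + 2 * D:2, b:b + 2 * H:2, c:c + 2 * W_:2, :])
                    dW[a, b, c] = xmat.T @ ds.reshape(-1, self.c_out)
                    dx += np.matmul(ds, Wk[a, b, c].T)
        self.grads = {"W": dW, "b": dy.sum(axis=(0, 1, 2, 3))}
        self._cache = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over the batch and spatial axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        # running statistics are state, not trainable parameters
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 1, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        out = xhat * self.params["gamma"] + self.params["beta"]
        if training:
            self._cache = (xhat, inv.astype(np.float32), x.shape)
        return out.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        axes = (0, 1, 2, 3)
        m = float(np.prod([shape[i] for i in axes]))
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        self.grads = {"gamma": dgamma, "beta": dbeta}
        g = self.params["gamma"]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) * inv
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, D, H, W_, C = x.shape
        r = x.reshape(N, D // 2, 2, H // 2, 2, W_ // 2, 2, C)
        r = r.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(N, D // 2, H // 2, W_ // 2, C, 8)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        N, D, H, W_, C = shape
        dr = np.zeros((N, D // 2, H // 2, W_ // 2, C, 8), dtype=dy.dtype)
        np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(N, D // 2, H // 2, W_ // 2, C, 2, 2, 2)
        dx = dr.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(shape)
        self._cache = None
        return np.ascontiguousarray(dx)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean per-voxel cross-entropy of integer labels, and its logit gradient."""
    p = softmax(logits)
    n = labels.size
    flat_p = p.reshape(n, -1)
    flat_l = labels.reshape(n).astype(np.intp)
    picked = np.clip(flat_p[np.arange(n), flat_l], 1e-12, None)
    loss = float(-np.log(picked).mean())
    grad = flat_p.copy()
    grad[np.arange(n), flat_l] -= 1.0
    grad /= n
    return loss, grad.reshape(logits.shape).astype(np.float32)
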