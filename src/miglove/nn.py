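"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the motor-imagery decoder needs: dense layers, layer/batch
normalization, dropout, scaled-dot-product multi-head attention, and an
Adam optimizer.  Every layer caches its forward activations and implements
``backward`` returning the gradient with respect to its input; parameter
gradients accumulate in ``layer.grads`` (reset by ``zero_grad``).  All
arithmetic is float64, so gradient checks against central differences pass
to ~1e-8.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Dense", "ReLU", "Dropout", "LayerNorm", "BatchNorm",
    "MultiHeadAttention", "Adam",
]


class Layer:
    """Base class: parameterless layers override forward/backward only."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis; Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.params = {
            "W": rng.uniform(-limit, limit, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.zero_grad()

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        x = self._x
        self.grads["W"] += np.tensordot(
            x.reshape(-1, x.shape[-1]), grad.reshape(-1, grad.shape[-1]),
            axes=(0, 0))
        self.grads["b"] += grad.reshape(-1, grad.shape[-1]).sum(axis=0)
        return grad @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class LayerNorm(Layer):
    """Normalize over the last axis; learned scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.zero_grad()

    def forward(self, x, training=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        g = self.params["gamma"]
        axes = tuple(range(grad.ndim - 1))
        self.grads["gamma"] += (grad * xhat).sum(axis=axes)
        self.grads["beta"] += grad.sum(axis=axes)
        gx = grad * g
        n = xhat.shape[-1]
        return (inv / n) * (
            n * gx
            - gx.sum(axis=-1, keepdims=True)
            - xhat * (gx * xhat).sum(axis=-1, keepdims=True)
        )


class BatchNorm(Layer):
    """Batch normalization over axis 0 for 2-D inputs.

    Keeps running mean/variance for evaluation; those running statistics
    count as (non-trainable) parameters, matching the usual framework
    bookkeeping of 4 x features.
    """

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.running = {"mean": np.zeros(dim), "var": np.ones(dim)}
        self.zero_grad()

    def n_params(self) -> int:
        return super().n_params() + sum(v.size for v in self.running.values())

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running["mean"] = (self.momentum * self.running["mean"]
                                    + (1 - self.momentum) * mu)
            self.running["var"] = (self.momentum * self.running["var"]
                                   + (1 - self.momentum) * var)
        else:
            mu, var = self.running["mean"], self.running["var"]
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        self._training = training
        return self._xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += (grad * xhat).sum(axis=0)
        self.grads["beta"] += grad.sum(axis=0)
        gx = grad * self.params["gamma"]
        if not self._training:
            return gx * inv
        n = xhat.shape[0]
        return (inv / n) * (
            n * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0)
        )


def _softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadAttention(Layer):
    """Scaled dot-product self-attention with per-head width ``head_size``.

    Query/key/value projections map ``embed_dim`` to
    ``n_heads * head_size`` (with biases); the concatenated heads are
    projected back to ``embed_dim``.  For embed_dim 16, 4 heads of size 64
    this is 3 x (16*256 + 256) + 256*16 + 16 = 17,168 parameters.
    """

    def __init__(self, embed_dim: int, n_heads: int, head_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.h, self.d = n_heads, head_size
        width = n_heads * head_size
        limit_in = np.sqrt(6.0 / (embed_dim + width))
        limit_out = np.sqrt(6.0 / (width + embed_dim))
        self.params = {
            "Wq": rng.uniform(-limit_in, limit_in, (embed_dim, width)),
            "bq": np.zeros(width),
            "Wk": rng.uniform(-limit_in, limit_in, (embed_dim, width)),
            "bk": np.zeros(width),
            "Wv": rng.uniform(-limit_in, limit_in, (embed_dim, width)),
            "bv": np.zeros(width),
            "Wo": rng.uniform(-limit_out, limit_out, (width, embed_dim)),
            "bo": np.zeros(embed_dim),
        }
        self.zero_grad()

    def _split(self, x):  # (B,S,H*D) -> (B,H,S,D)
        b, s, _ = x.shape
        return x.reshape(b, s, self.h, self.d).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B,H,S,D) -> (B,S,H*D)
        b, h, s, d = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, s, h * d)

    def forward(self, x, training=False):
        p = self.params
        self._x = x
        self._q = self._split(x @ p["Wq"] + p["bq"])
        self._k = self._split(x @ p["Wk"] + p["bk"])
        self._v = self._split(x @ p["Wv"] + p["bv"])
        self._scale = 1.0 / np.sqrt(self.d)
        scores = (self._q @ self._k.transpose(0, 1, 3, 2)) * self._scale
        self._attn = _softmax_last(scores)
        self._ctx = self._merge(self._attn @ self._v)
        return self._ctx @ p["Wo"] + p["bo"]

    def backward(self, grad):
        p = self.params
        b, s, e = grad.shape
        self.grads["Wo"] += np.tensordot(self._ctx.reshape(-1, self.h * self.d),
                                         grad.reshape(-1, e), axes=(0, 0))
        self.grads["bo"] += grad.reshape(-1, e).sum(axis=0)
        g_ctx = self._split(grad @ p["Wo"].T)            # (B,H,S,D)
        g_attn = g_ctx @ self._v.transpose(0, 1, 3, 2)   # (B,H,S,S)
        g_v = self._attn.transpose(0, 1, 3, 2) @ g_ctx
        a = self._attn
        g_scores = a * (g_attn - (g_attn * a).sum(axis=-1, keepdims=True))
        g_scores *= self._scale
        g_q = g_scores @ self._k
        g_k = g_scores.transpose(0, 1, 3, 2) @ self._q
        gx = np.zeros_like(self._x)
        for name, g_head in (("Wq", g_q), ("Wk", g_k), ("Wv", g_v)):
            g_flat = self._merge(g_head).reshape(-1, self.h * self.d)
            x_flat = self._x.reshape(-1, e)
            self.grads[name] += np.tensordot(x_flat, g_flat, axes=(0, 0))
            self.grads["b" + name[1:].lower()] += g_flat.sum(axis=0)
            gx += self._merge(g_head) @ p[name].T
        return gx


class Adam:
    """Adam over a list of layers (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
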