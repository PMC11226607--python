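"""Minimal numpy neural-network layers with explicit forward/backward passes.

All image tensors are NHWC float64 arrays. Every layer caches what its
backward pass needs during ``forward``; ``backward`` consumes the gradient
w.r.t. the layer output and returns the gradient w.r.t. the input, while
accumulating parameter gradients on the layer. This explicit-backprop design
keeps gradients available at intermediate stages (needed for Grad-CAM) and
is verified end-to-end against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "AvgPool2d",
    "BilinearUpsample",
    "Dense",
    "LayerNorm",
    "BatchNorm1d",
    "Dropout",
    "bilinear_matrix",
    "adaptive_bins",
    "glorot_uniform",
    "SGD",
    "softmax",
    "softmax_cross_entropy",
]


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter-free identity."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad

    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, grad) triples; values are mutated in place by optimizers."""
        return []

    def zero_grad(self) -> None:
        for _, _, g in self.parameters():
            g[...] = 0.0

    @property
    def n_parameters(self) -> int:
        return sum(int(p.size) for _, p, _ in self.parameters())


class Conv2d(Layer):
    """2-D convolution on NHWC tensors, implemented by kernel-offset slicing."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in, fan_out = k * k * in_channels, k * k * out_channels
        self.W = glorot_uniform(rng, fan_in, fan_out, (k, k, in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel_size, self.stride, self.padding = k, stride, padding
        self.in_channels, self.out_channels = in_channels, out_channels

    def parameters(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x, train=False):
        k, s, p = self.kernel_size, self.stride, self.padding
        if x.ndim != 4 or x.shape[3] != self.in_channels:
            raise ValueError(
                f"expected NHWC input with {self.in_channels} channels, got {x.shape}")
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xpad = x
        n, hp, wp, _ = x.shape
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        out = np.broadcast_to(self.b, (n, ho, wo, self.out_channels)).copy()
        for ki in range(k):
            for kj in range(k):
                patch = x[:, ki:ki + ho * s:s, kj:kj + wo * s:s, :]
                out += np.einsum("nhwc,cf->nhwf", patch, self.W[ki, kj], optimize=True)
        return out

    def backward(self, grad):
        k, s, p = self.kernel_size, self.stride, self.padding
        x = self._xpad
        n, hp, wp, _ = x.shape
        ho, wo = grad.shape[1], grad.shape[2]
        dx = np.zeros_like(x)
        self.db += grad.sum(axis=(0, 1, 2))
        for ki in range(k):
            for kj in range(k):
                patch = x[:, ki:ki + ho * s:s, kj:kj + wo * s:s, :]
                self.dW[ki, kj] += np.einsum("nhwc,nhwf->cf", patch, grad, optimize=True)
                dx[:, ki:ki + ho * s:s, kj:kj + wo * s:s, :] += np.einsum(
                    "nhwf,cf->nhwc", grad, self.W[ki, kj], optimize=True)
        if p:
            dx = dx[:, p:-p, p:-p, :]
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool2d(Layer):
    """Non-overlapping average pooling; spatial size must be divisible by `size`."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train=False):
        s = self.size
        n, h, w, c = x.shape
        if h % s or w % s:
            raise ValueError(f"spatial size {(h, w)} not divisible by pool size {s}")
        self._in_shape = x.shape
        return x.reshape(n, h // s, s, w // s, s, c).mean(axis=(2, 4))

    def backward(self, grad):
        s = self.size
        n, h, w, c = self._in_shape
        g = grad[:, :, None, :, None, :] / (s * s)
        return np.broadcast_to(g, (n, h // s, s, w // s, s, c)).reshape(n, h, w, c)


def bilinear_matrix(target: int, source: int) -> np.ndarray:
    """Row-stochastic (target x source) bilinear interpolation matrix.

    Half-pixel-center convention (no corner alignment); reduces to the
    identity when target == source.
    """
    if target < source:
        raise ValueError("bilinear_matrix used for upsampling only (target >= source)")
    R = np.zeros((target, source))
    for i in range(target):
        src = (i + 0.5) * source / target - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        i0c = min(max(i0, 0), source - 1)
        i1c = min(max(i0 + 1, 0), source - 1)
        R[i, i0c] += 1.0 - frac
        R[i, i1c] += frac
    return R


class BilinearUpsample(Layer):
    """Separable bilinear resize of NHWC maps to a fixed (H, W) target."""

    def __init__(self, source: tuple[int, int], target: tuple[int, int]):
        h, w = source
        H, W = target
        if H < h or W < w:
            raise ValueError(f"target {target} smaller than source {source}")
        self.Rh = bilinear_matrix(H, h)
        self.Rw = bilinear_matrix(W, w)

    def forward(self, x, train=False):
        return np.einsum("th,nhwc,uw->ntuc", self.Rh, x, self.Rw, optimize=True)

    def backward(self, grad):
        return np.einsum("th,ntuc,uw->nhwc", self.Rh, grad, self.Rw, optimize=True)


def adaptive_bins(n_bins: int, size: int) -> list[tuple[int, int]]:
    """[start, end) spans of adaptive pooling bins: bin b covers
    [floor(b*size/n), ceil((b+1)*size/n))."""
    return [(int(np.floor(b * size / n_bins)), int(np.ceil((b + 1) * size / n_bins)))
            for b in range(n_bins)]


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = glorot_uniform(rng, in_features, out_features, (in_features, out_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T


class LayerNorm(Layer):
    """Normalization over the feature axis of (N, C) inputs."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps = eps

    def parameters(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x, train=False):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        self.dgamma += (grad * xhat).sum(axis=0)
        self.dbeta += grad.sum(axis=0)
        gh = grad * self.gamma
        d = gh.shape[1]
        return inv * (gh - gh.mean(axis=1, keepdims=True)
                      - xhat * (gh * xhat).mean(axis=1, keepdims=True)) \
            if d > 1 else np.zeros_like(grad)


class BatchNorm1d(Layer):
    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.eps, self.momentum = eps, momentum

    def parameters(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._train = train
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        self.dgamma += (grad * xhat).sum(axis=0)
        self.dbeta += grad.sum(axis=0)
        gh = grad * self.gamma
        if not self._train:
            return gh * inv
        n = gh.shape[0]
        return inv * (gh - gh.mean(axis=0) - xhat * (gh * xhat).mean(axis=0)) \
            if n > 1 else gh * inv


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray,
                          floor: float = 1e-12) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean categorical cross-entropy; returns (loss, probs, dlogits)."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(onehot * np.log(np.clip(probs, floor, 1.0))) / n
    return float(loss), probs, (probs - onehot) / n


class SGD:
    """Stochastic gradient descent with optional classical momentum."""

    def __init__(self, layers, lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.layers = layers
        self.lr = lr
        self.momentum = momentum
        self._velocity = {}

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def step(self):
        for li, layer in enumerate(self.layers):
            for pi, (name, value, grad) in enumerate(layer.parameters()):
                key = (li, pi)
                if self.momentum:
                    v = self._velocity.get(key)
                    if v is None:
                        v = np.zeros_like(value)
                    v = self.momentum * v - self.lr * grad
                    self._velocity[key] = v
                    value += v
                else:
                    value -= self.lr * grad
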