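"""Minimal CPU convolutional-network framework (numpy, manual backprop).

Provides exactly the building blocks the image-to-image GAN needs:
strided 2D convolutions (im2col + matmul), nearest-neighbor upsampling,
leaky ReLU, instance normalization, an Adam optimizer, and a numerically
stable binary cross-entropy on logits.  Arrays are float32 in
(batch, channel, height, width) layout.  Every layer caches what its
backward pass needs; ``backward`` consumes the output gradient and
returns the input gradient while accumulating parameter gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "Upsample2x", "LeakyReLU", "InstanceNorm", "Sequential",
           "Adam", "bce_with_logits", "sigmoid"]

F32 = np.float32


def _im2col(x, k, stride, pad):
    """(B,C,H,W) -> columns (C*k*k, B*Ho*Wo) plus output spatial shape.

    Channel-major layout: the result feeds one BLAS GEMM covering the
    whole batch, with a single copy.
    """
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = x.shape[2], x.shape[3]
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]          # B,C,Ho,Wo,k,k
    cols = windows.transpose(1, 4, 5, 0, 2, 3).reshape(C * k * k, B * Ho * Wo)
    return np.ascontiguousarray(cols), (Ho, Wo)


def _col2im(dflat, xshape, k, stride, pad, out_hw):
    """Scatter column gradients (C*k*k, B*L) back onto the input."""
    B, C, H, W = xshape
    Ho, Wo = out_hw
    d = dflat.reshape(C, k, k, B, Ho, Wo)
    dx = np.zeros((C, B, H + 2 * pad, W + 2 * pad), dtype=F32)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + stride * Ho:stride,
               j:j + stride * Wo:stride] += d[:, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return np.ascontiguousarray(dx.transpose(1, 0, 2, 3))


class Layer:
    params: tuple = ()

    def forward(self, x, train=True):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Conv2d(Layer):
    """Strided 2D convolution; He-style initialization."""

    def __init__(self, cin, cout, k=3, stride=1, pad=None, rng=None):
        rng = rng or np.random.default_rng()
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin * k * k)) * scale).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = ((self.W, self.dW), (self.b, self.db))

    def forward(self, x, train=True):
        x = x.astype(F32, copy=False)
        flat, (Ho, Wo) = _im2col(x, self.k, self.stride, self.pad)
        B = x.shape[0]
        out = self.W @ flat + self.b[:, None]
        if train:
            self._cache = (flat, x.shape, (Ho, Wo))
        return out.reshape(-1, B, Ho, Wo).swapaxes(0, 1)

    def backward(self, grad):
        flat, xshape, out_hw = self._cache
        B, cout = grad.shape[0], grad.shape[1]
        g = np.ascontiguousarray(grad.swapaxes(0, 1)).reshape(cout, -1)
        self.dW += g @ flat.T
        self.db += g.sum(axis=1)
        dflat = self.W.T @ g
        return _col2im(dflat, xshape, self.k, self.stride, self.pad, out_hw)


class Upsample2x(Layer):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad):
        B, C, H, W = grad.shape
        return grad.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x, train=True):
        if train:
            self._neg = x < 0
        return np.where(x < 0, self.slope * x, x)

    def backward(self, grad):
        return np.where(self._neg, self.slope * grad, grad)


class InstanceNorm(Layer):
    """Per-sample per-channel normalization with learnable affine."""

    EPS = 1e-5

    def __init__(self, c):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.params = ((self.gamma, self.dgamma), (self.beta, self.dbeta))

    def forward(self, x, train=True):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        xhat = (x - mu) / np.sqrt(var + self.EPS)
        if train:
            self._cache = (xhat, var)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, var = self._cache
        self.dgamma += (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        inv = 1.0 / np.sqrt(var + self.EPS)
        return inv * (g - g.mean(axis=(2, 3), keepdims=True)
                      - xhat * (g * xhat).mean(axis=(2, 3), keepdims=True))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)
        self.params = tuple(p for l in self.layers for p in l.params)

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Adam:
    """Adam with the beta1=0.5 convention common for GAN training."""

    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z, target):
    """Mean binary cross-entropy on logits and its gradient w.r.t. z."""
    t = float(target) if np.isscalar(target) else target
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - t) / z.size
    return float(loss), grad.astype(F32)
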