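"""Minimal NumPy convolutional-network engine.

Self-contained building blocks (3x3 same-padding convolution via
im2col + BLAS matmul, batch normalization, ReLU, 2x2 max pooling, 2x2
transposed-convolution upsampling, skip concatenation) with explicit
backward passes, plus an Adam optimizer and a masked L1 loss.  All
tensors are NHWC float32; determinism is exact given the seed because
everything reduces to dense BLAS calls.

The engine exists to train the 2D U-Net estimator; it is deliberately
small — no autograd graph, layers are composed explicitly by the
network class and gradients flow through ``backward`` calls in reverse
order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "BatchNorm", "ReLU", "MaxPool2", "UpConv2", "Adam",
           "masked_l1_loss"]

F32 = np.float32


def _he_init(rng, fan_in, shape):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv3x3:
    """3x3 convolution, stride 1, zero 'same' padding, NHWC."""

    def __init__(self, c_in: int, c_out: int, rng):
        self.w = _he_init(rng, 9 * c_in, (9 * c_in, c_out))
        self.b = np.zeros(c_out, dtype=F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.c_in, self.c_out = c_in, c_out

    def _im2col(self, x):
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        s = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, (b, h, w, 3, 3, c), (s[0], s[1], s[2], s[1], s[2], s[3]))
        return win.reshape(b * h * w, 9 * c)

    def forward(self, x, train=True):
        self.x_shape = x.shape
        cols = self._im2col(x)
        if train:
            self.cols = cols
        b, h, w, _ = x.shape
        return (cols @ self.w + self.b).reshape(b, h, w, self.c_out)

    def backward(self, dy):
        b, h, w, _ = self.x_shape
        dyf = dy.reshape(b * h * w, self.c_out)
        self.grads[0][...] = self.cols.T @ dyf
        self.grads[1][...] = dyf.sum(0)
        # dx: scatter dy @ W[di,dj].T into a padded buffer (9 tap positions)
        wr = self.w.reshape(3, 3, self.c_in, self.c_out)
        dxp = np.zeros((b, h + 2, w + 2, self.c_in), dtype=F32)
        for di in range(3):
            for dj in range(3):
                contrib = dyf @ wr[di, dj].T
                dxp[:, di:di + h, dj:dj + w, :] += contrib.reshape(b, h, w, self.c_in)
        self.cols = None
        return dxp[:, 1:h + 1, 1:w + 1, :]


class BatchNorm:
    """Per-channel batch normalization over (N, H, W) with running stats."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        self.inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self.xhat = (x - mu) * self.inv
        return self.gamma * self.xhat + self.beta

    def backward(self, dy):
        n = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.grads[0][...] = (dy * self.xhat).sum(axis=(0, 1, 2))
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma
        dx = (self.inv / n) * (
            n * dxhat - dxhat.sum(axis=(0, 1, 2))
            - self.xhat * (dxhat * self.xhat).sum(axis=(0, 1, 2)))
        self.xhat = None
        return dx.astype(F32)


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train=True):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dy):
        out = dy * self.mask
        self.mask = None
        return out


class MaxPool2:
    """2x2 max pooling, stride 2."""

    params: list = []
    grads: list = []

    def forward(self, x, train=True):
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        # winner mask; exact float ties would split the gradient (harmless, rare)
        self.mask = xr == out[:, :, None, :, None, :]
        self.x_shape = x.shape
        return out

    def backward(self, dy):
        b, h, w, c = self.x_shape
        dx = self.mask * dy[:, :, None, :, None, :]
        self.mask = None
        return dx.reshape(b, h, w, c).astype(F32, copy=False)


class UpConv2:
    """2x2 transposed convolution, stride 2 (each pixel emits a 2x2 block)."""

    def __init__(self, c_in: int, c_out: int, rng):
        self.w = _he_init(rng, c_in, (c_in, 4 * c_out))  # 4 = the 2x2 block
        self.b = np.zeros(c_out, dtype=F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train=True):
        b, h, w, c = x.shape
        self.x = x if train else None
        self.x_shape = x.shape
        blocks = (x.reshape(b * h * w, c) @ self.w).reshape(b, h, w, 2, 2, self.c_out)
        out = blocks.transpose(0, 1, 3, 2, 4, 5).reshape(b, 2 * h, 2 * w, self.c_out)
        return out + self.b

    def backward(self, dy):
        b, h, w, c = self.x_shape
        dblocks = dy.reshape(b, h, 2, w, 2, self.c_out).transpose(0, 1, 3, 2, 4, 5)
        dflat = dblocks.reshape(b * h * w, 4 * self.c_out)
        self.grads[0][...] = self.x.reshape(b * h * w, c).T @ dflat
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        dx = dflat @ self.w.T
        self.x = None
        return dx.reshape(b, h, w, c)


class Adam:
    """Adam optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = [(p, g) for layer in layers for p, g in zip(layer.params, layer.grads)]
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def masked_l1_loss(pred, target, mask):
    """Mean absolute error over voxels where ``mask`` is True.

    Returns ``(loss, dpred)``; masked-out voxels contribute neither to
    the loss nor to the gradient.
    """
    n = int(mask.sum())
    if n == 0:
        return 0.0, np.zeros_like(pred)
    diff = (pred - target) * mask
    loss = float(np.abs(diff).sum() / n)
    dpred = (np.sign(diff) / n).astype(F32)
    return loss, dpred
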