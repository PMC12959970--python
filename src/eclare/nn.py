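"""Minimal CPU neural-network layers with explicit backpropagation.

The per-volume self-training loop needs only a handful of primitives:
same-padded 2-D convolutions, ReLU, dense layers, average pooling, Adam
and a one-cycle learning-rate schedule.  They are implemented here
directly on numpy arrays with hand-written gradients — forward passes
cache what the backward pass needs, and every layer exposes its
parameters and gradient buffers to the optimizer.  All arithmetic is
plain seeded numpy at a fixed dtype, so training is bit-reproducible on
CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "Dense",
    "AvgPool2",
    "Flatten",
    "Sequential",
    "Adam",
    "OneCycleSchedule",
]


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self):
        """Yield (param_array, grad_array) pairs; arrays are updated in place."""
        return ()


class Conv2d(Layer):
    """3x3 (or kxk) same-padded stride-1 convolution on (B, C, H, W) arrays.

    ``dtype`` float32 halves memory traffic (the training loop is
    bandwidth/compute bound on CPU); float64 is available where bit-exact
    agreement with the float64 resampling operators matters.
    """

    def __init__(self, c_in, c_out, ksize=3, rng=None, zero_init=False,
                 dtype=np.float32):
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        self.dtype = np.dtype(dtype)
        fan_in = c_in * ksize * ksize
        if zero_init:
            w = np.zeros((fan_in, c_out))
        else:
            rng = rng if rng is not None else np.random.default_rng(0)
            # He initialization for ReLU trunks
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.w = w.astype(self.dtype)    # (C_in*k*k, C_out)
        self.b = np.zeros(c_out, dtype=self.dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        b, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (B, H, W, C, k, k) view -> (B*H*W, C*k*k)
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * self.k * self.k)
        out = cols @ self.w + self.b
        self._cols, self._shape = cols, (b, c, h, w)
        return out.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        p, k = self.k // 2, self.k
        g2 = np.ascontiguousarray(
            grad.transpose(0, 2, 3, 1), dtype=self.dtype
        ).reshape(b * h * w, self.c_out)
        self.gw[...] = self._cols.T @ g2
        self.gb[...] = g2.sum(axis=0)
        dcols = (g2 @ self.w.T).reshape(b, h, w, c, k, k)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=self.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w]

    def parameters(self):
        return ((self.w, self.gw), (self.b, self.gb))


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None, zero_init=False, dtype=np.float64):
        dtype = np.dtype(dtype)
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            rng = rng if rng is not None else np.random.default_rng(0)
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.w, self.b = w.astype(dtype), np.zeros(n_out, dtype=dtype)
        self.gw, self.gb = np.zeros_like(self.w), np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def parameters(self):
        return ((self.w, self.gw), (self.b, self.gb))


class AvgPool2(Layer):
    """2x2 average pooling (floor division of spatial dims)."""

    def forward(self, x):
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._shape = x.shape
        xc = x[:, :, : 2 * h2, : 2 * w2].reshape(b, c, h2, 2, w2, 2)
        return xc.mean(axis=(3, 5))

    def backward(self, grad):
        b, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(self._shape)
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        dx[:, :, : 2 * h2, : 2 * w2] = g
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()


class Adam:
    """Adam with in-place parameter updates; lr is read per-step."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class OneCycleSchedule:
    """One-cycle learning rate: cosine warmup to max_lr, cosine anneal down.

    Standard shape: start at max_lr / div_factor, rise for pct_start of the
    steps, then anneal to max_lr / final_div.
    """

    def __init__(self, max_lr, total_steps, pct_start=0.3, div_factor=25.0,
                 final_div=1e4):
        self.max_lr = max_lr
        self.total_steps = max(1, int(total_steps))
        self.pct_start = pct_start
        self.initial_lr = max_lr / div_factor
        self.final_lr = max_lr / final_div

    def lr_at(self, step: int) -> float:
        up = max(1, int(self.total_steps * self.pct_start))
        if step < up:
            frac = step / up
            lo, hi = self.initial_lr, self.max_lr
        else:
            down = max(1, self.total_steps - up)
            frac = min(1.0, (step - up) / down)
            lo, hi = self.max_lr, self.final_lr
            return lo + (hi - lo) * 0.5 * (1 - np.cos(np.pi * frac))
        return lo + (hi - lo) * 0.5 * (1 - np.cos(np.pi * frac))
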