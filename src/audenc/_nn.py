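"""Minimal 1-D CNN primitives on numpy: conv, switch max-pooling, Adam.

Array convention: a batch of 1-D multichannel signals is ``(n, t, c)``
(batch, time, channels). Convolutions are stride-1 with "same" padding so
conv layers preserve temporal length; all temporal reduction happens in
pooling. Weights are ``(k, c_in, c_out)``.

The forward pass uses an im2col layout (``sliding_window_view`` + matmul)
which makes the backward pass a pair of matmuls plus a k-tap scatter.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# convolution


def _pad_same(x: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    left = (k - 1) // 2
    right = k - 1 - left
    return np.pad(x, ((0, 0), (left, right), (0, 0))), left


def conv1d_forward(x, W, b, *, return_cols=False):
    """Same-padding stride-1 convolution (cross-correlation).

    x: (n, t, c_in); W: (k, c_in, c_out); b: (c_out,). Returns (n, t, c_out)
    and, optionally, the im2col tensor needed for the backward pass.
    """
    n, t, c_in = x.shape
    k, _, c_out = W.shape
    xp, _ = _pad_same(x, k)
    # (n, t, k, c_in): window j of tap-k slices, channel-last
    cols = sliding_window_view(xp, k, axis=1).transpose(0, 1, 3, 2)
    y = cols.reshape(n * t, k * c_in) @ W.reshape(k * c_in, c_out) + b
    y = y.reshape(n, t, c_out)
    return (y, cols) if return_cols else (y, None)


def conv1d_backward(dy, cols, W, x_shape):
    """Gradients of conv1d_forward. Returns (dx, dW, db)."""
    n, t, c_in = x_shape
    k, _, c_out = W.shape
    dyf = dy.reshape(n * t, c_out)
    dW = (cols.reshape(n * t, k * c_in).T @ dyf).reshape(k, c_in, c_out)
    db = dyf.sum(axis=0)
    dcols = (dyf @ W.reshape(k * c_in, c_out).T).reshape(n, t, k, c_in)
    left = (k - 1) // 2
    dxp = np.zeros((n, t + k - 1, c_in))
    for j in range(k):  # scatter-add the k overlapping taps
        dxp[:, j : j + t, :] += dcols[:, :, j, :]
    dx = dxp[:, left : left + t, :]
    return dx, dW, db


# ---------------------------------------------------------------------------
# pooling with switches


def max_pool(x, factor):
    """Max-pool over time with argmax switches.

    x: (n, t, c). Returns (pooled (n, t//factor, c), switches) where
    switches hold each region's within-region argmax offset (leftmost
    maximum on ties). Inputs whose length is not divisible by ``factor``
    are right-truncated first. ``factor=1`` is the identity.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"pool factor must be a positive integer, got {factor}")
    factor = int(factor)
    n, t, c = x.shape
    tp = t // factor
    if tp < 1:
        raise ValueError(f"input length {t} shorter than pool factor {factor}")
    xr = x[:, : tp * factor, :].reshape(n, tp, factor, c)
    switches = xr.argmax(axis=2)
    pooled = np.take_along_axis(xr, switches[:, :, None, :], axis=2)[:, :, 0, :]
    return pooled, switches


def max_unpool(pooled, switches, factor):
    """Invert max_pool: place each max at its recorded offset, zeros elsewhere."""
    factor = int(factor)
    n, tp, c = pooled.shape
    if switches.shape != (n, tp, c):
        raise ValueError(
            f"switches shape {switches.shape} does not match pooled {pooled.shape}"
        )
    if np.any(switches < 0) or np.any(switches >= factor):
        raise ValueError("switch offsets fall outside their pooling regions")
    out = np.zeros((n, tp, factor, c))
    np.put_along_axis(out, switches[:, :, None, :], pooled[:, :, None, :], axis=2)
    return out.reshape(n, tp * factor, c)


def max_pool_backward(dpooled, switches, factor):
    """Route pooled gradients back to the argmax positions (= unpool)."""
    return max_unpool(dpooled, switches, factor)


def max_unpool_backward(dx, switches, factor):
    """Gather gradients from the switch positions (= pool by switches)."""
    factor = int(factor)
    n, t, c = dx.shape
    tp = t // factor
    xr = dx.reshape(n, tp, factor, c)
    return np.take_along_axis(xr, switches[:, :, None, :], axis=2)[:, :, 0, :]


# ---------------------------------------------------------------------------
# activations


def relu(x):
    return np.maximum(x, 0.0)


def relu_backward(dy, y):
    return dy * (y > 0)


# ---------------------------------------------------------------------------
# optimizer


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay multiplies weights by ``(1 - lr * wd)`` each step,
    separately from the gradient moments; it is applied only to
    parameters registered with ``decay=True`` (conv weights, not biases).
    """

    def __init__(self, lr=2e-4, beta_1=0.5, beta_2=0.999, eps=1e-8, weight_decay=0.0):
        self.lr = lr
        self.beta_1 = beta_1
        self.beta_2 = beta_2
        self.eps = eps
        self.weight_decay = weight_decay
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._t = 0

    def step(self, params, grads, decay_flags):
        """Update params in place. All three sequences are aligned."""
        self._t += 1
        b1, b2 = self.beta_1, self.beta_2
        for i, (p, g, dec) in enumerate(zip(params, grads, decay_flags)):
            if i not in self._state:
                self._state[i] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self._state[i]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            if dec and self.weight_decay:
                p *= 1.0 - self.lr * self.weight_decay
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot_uniform(shape, fan_in, fan_out, rng):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)
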