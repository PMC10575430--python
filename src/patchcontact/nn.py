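"""Minimal NHWC convolutional-network primitives in numpy.

Forward and backward passes are written explicitly (im2col convolutions
feeding BLAS matmuls, float32 throughout) so the defocus network trains on
a single CPU core in minutes with fully seeded, reproducible arithmetic.
Only the pieces the network needs exist: same-padded stride-1 convolution,
ReLU, 2x2 max pooling, nearest 2x upsampling, dense layers, and Adam.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None):
    """Same-padded stride-1 convolution.

    x: (N, H, W, Cin); w: (Cout, Cin, k, k) with odd k; returns
    (y, cols) where cols is the flattened patch matrix cached for the
    backward pass.
    """
    n, h, wd, cin = x.shape
    cout, cin_w, k, _ = w.shape
    assert cin == cin_w, (cin, cin_w)
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    # windows over spatial axes -> (N, H, W, Cin, k, k)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    cols = np.ascontiguousarray(win).reshape(n * h * wd, cin * k * k)
    wmat = w.transpose(1, 2, 3, 0).reshape(cin * k * k, cout)
    y = cols @ wmat
    if b is not None:
        y += b
    return y.reshape(n, h, wd, cout), cols


def conv2d_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray):
    """Gradients of conv2d: returns (dx, dw, db)."""
    n, h, wd, cout = dy.shape
    cin, k = w.shape[1], w.shape[2]
    dy_flat = dy.reshape(n * h * wd, cout)
    dwmat = cols.T @ dy_flat  # (Cin*k*k, Cout)
    dw = dwmat.reshape(cin, k, k, cout).transpose(3, 0, 1, 2)
    db = dy_flat.sum(axis=0)
    # dx: full correlation of dy with spatially flipped, channel-swapped w
    w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, k, k)
    dx, _ = conv2d(dy, np.ascontiguousarray(w_flip))
    return dx, dw.astype(F32), db.astype(F32)


def maxpool2(x: np.ndarray):
    """2x2 max pooling; returns (y, cache)."""
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    y = xr.max(axis=(2, 4))
    return y, (xr, y)


def maxpool2_backward(dy: np.ndarray, cache):
    xr, y = cache
    winners = xr == y[:, :, None, :, None, :]
    # split gradient evenly among ties (valid subgradient)
    counts = winners.sum(axis=(2, 4), keepdims=True)
    g = winners * (dy[:, :, None, :, None, :] / counts)
    n, hh, _, ww, _, c = xr.shape
    return g.reshape(n, hh * 2, ww * 2, c)


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling."""
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, h, w, c = dy.shape
    return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def relu(x: np.ndarray):
    y = np.maximum(x, 0)
    return y, y > 0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable mean binary cross entropy on logits.

    Returns (loss, dloss/dz)."""
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - y) / z.size
    return float(loss.mean()), dz.astype(F32)


def he_init(rng: np.random.Generator, cout: int, cin: int, k: int) -> np.ndarray:
    std = np.sqrt(2.0 / (cin * k * k))
    return rng.normal(0.0, std, (cout, cin, k, k)).astype(F32)


class Adam:
    """Adam optimiser over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
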