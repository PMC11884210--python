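"""Minimal CNN building blocks in numpy with hand-written backpropagation.

Everything operates on float32 batches in (N, C, H, W) layout. Convolutions
use im2col (stride-tricks windows + one matmul); the backward pass for the
input is itself a convolution with channel-transposed, spatially flipped
kernels, so no explicit col2im scatter is needed. Only the pieces the 2D
U-Net needs are implemented: same-padding odd-kernel convolution, ReLU,
2x2 max pooling, 2x2-stride-2 transposed convolution, channel
concatenation, and a softmax cross-entropy head.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for 'same' padding."""
    N, C, H, W = x.shape
    if k == 1:
        return x.transpose(0, 2, 3, 1).reshape(N * H * W, C)
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * H * W, C * k * k
    )


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding 2D convolution; w is (F, C, k, k), b is (F,)."""
    N, C, H, W = x.shape
    F, _, k, _ = w.shape
    cols = _im2col(x, k)
    out = cols @ w.reshape(F, -1).T + b
    return out.reshape(N, H, W, F).transpose(0, 3, 1, 2)


def conv2d_backward(
    dout: np.ndarray, x: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of a same-padding convolution."""
    N, C, H, W = x.shape
    F, _, k, _ = w.shape
    dout_flat = dout.transpose(0, 2, 3, 1).reshape(-1, F)
    cols = _im2col(x, k)
    dw = (dout_flat.T @ cols).reshape(w.shape)
    db = dout_flat.sum(axis=0)
    # dx = 'full' correlation of dout with flipped, channel-transposed kernels
    w_flip = np.ascontiguousarray(w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dx = conv2d_forward(dout, w_flip, np.zeros(C, dtype=w.dtype))
    return dx, dw, db


def relu_forward(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def relu_backward(dout: np.ndarray, out: np.ndarray) -> np.ndarray:
    return dout * (out > 0)


def maxpool2_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling with stride 2; H and W must be even.

    Returns (pooled, argmax) where argmax in {0..3} selects the winning
    pixel inside each 2x2 window (first on ties).
    """
    N, C, H, W = x.shape
    xr = (
        x.reshape(N, C, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, H // 2, W // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def maxpool2_backward(dout: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    N, C, H, W = in_shape
    dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return (
        dxr.reshape(N, C, H // 2, W // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, H, W)
    )


def upconv2_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """2x2 transposed convolution with stride 2; w is (Cin, Cout, 2, 2)."""
    N, C, H, W = x.shape
    F = w.shape[1]
    y = np.einsum("ncij,cfde->nfidje", x, w, optimize=True)
    out = y.reshape(N, F, 2 * H, 2 * W) + b[None, :, None, None]
    return out


def upconv2_backward(
    dout: np.ndarray, x: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    N, C, H, W = x.shape
    F = w.shape[1]
    dyr = dout.reshape(N, F, H, 2, W, 2)  # (n, f, i, d, j, e)
    dx = np.einsum("nfidje,cfde->ncij", dyr, w, optimize=True)
    dw = np.einsum("ncij,nfidje->cfde", x, dyr, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    return dx, dw, db


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax over axis 1 of (N, K, H, W)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean pixel-wise cross entropy and its gradient w.r.t. the logits.

    targets is an (N, H, W) integer class map.
    """
    N, K, H, W = logits.shape
    p = softmax(logits)
    flat = p.transpose(0, 2, 3, 1).reshape(-1, K)
    t = targets.reshape(-1)
    eps = 1e-12
    loss = float(-np.mean(np.log(flat[np.arange(t.size), t] + eps)))
    grad_flat = flat.copy()
    grad_flat[np.arange(t.size), t] -= 1.0
    grad_flat /= t.size
    dlogits = grad_flat.reshape(N, H, W, K).transpose(0, 3, 1, 2)
    return loss, dlogits.astype(logits.dtype)


class AdamState:
    """Adam moment estimates for one parameter set."""

    def __init__(self, params: dict[str, np.ndarray]):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0


def clip_gradients_l2(grads: dict[str, np.ndarray], threshold: float) -> float:
    """Clip the global L2 norm of all gradients to ``threshold`` (in place).

    Returns the pre-clip norm.
    """
    total = float(np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values())))
    if threshold > 0 and total > threshold:
        scale = threshold / total
        for g in grads.values():
            g *= scale
    return total


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: AdamState,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    """One Adam update, in place."""
    state.t += 1
    t = state.t
    for k, p in params.items():
        g = grads[k]
        state.m[k] = beta1 * state.m[k] + (1 - beta1) * g
        state.v[k] = beta2 * state.v[k] + (1 - beta2) * g * g
        mhat = state.m[k] / (1 - beta1**t)
        vhat = state.v[k] / (1 - beta2**t)
        p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(p.dtype)


__all__ = [
    "conv2d_forward",
    "conv2d_backward",
    "relu_forward",
    "relu_backward",
    "maxpool2_forward",
    "maxpool2_backward",
    "upconv2_forward",
    "upconv2_backward",
    "softmax",
    "softmax_cross_entropy",
    "AdamState",
    "adam_step",
    "clip_gradients_l2",
]
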