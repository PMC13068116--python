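"""Minimal NumPy building blocks for the segmentation encoder-decoder.

Convolutions are implemented as im2col + BLAS matmul; the backward pass for
the input gradient reuses the same machinery as a full convolution with
spatially flipped, channel-transposed kernels.  Everything operates on
``(N, C, H, W)`` float64 arrays.  The blocks cache what they need on forward
and expose ``backward`` returning the input gradient while accumulating
parameter gradients in ``.grads``.

This is deliberately small: 3x3 and 1x1 convolutions with stride 1, ReLU,
2x2 max-pool, 2x nearest-neighbour upsampling, channel concatenation, a
weighted softmax cross-entropy head, and Adam.  It is enough to express a
UNet-style network at the frame sizes this package works with.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2x2", "Upsample2x", "Adam",
           "softmax", "weighted_softmax_ce"]


def _im2col(x: np.ndarray, ksize: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patch matrix, stride 1."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (ksize, ksize), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k) -> (N, H*W, C*k*k)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    return np.ascontiguousarray(win).reshape(n, h * w, c * ksize * ksize)


class Conv2d:
    """Stride-1 convolution with 'same' padding; ksize 3 or 1."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        fan_in = c_in * ksize * ksize
        # He initialization for ReLU nets; float32 keeps the BLAS calls cheap
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, ksize, ksize)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._xshape = x.shape
        cols = _im2col(x, self.ksize, self.ksize // 2)
        self._cols = cols
        wmat = self.w.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.b  # (N, H*W, C_out)
        return out.transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = dy.shape
        dy = dy.astype(self.w.dtype, copy=False)
        dy_mat = dy.reshape(n, self.c_out, h * w).transpose(0, 2, 1)  # (N, HW, C_out)
        self.grads["w"] += np.einsum("npo,npk->ok", dy_mat, self._cols).reshape(self.w.shape)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        # dx = conv(dy, flipped W transposed in channels)
        w_flip = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C_in, C_out, k, k)
        cols_dy = _im2col(dy, self.ksize, self.ksize // 2)
        dx = cols_dy @ w_flip.reshape(self.c_in, -1).T  # (N, HW, C_in)
        return dx.transpose(0, 2, 1).reshape(self._xshape)


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2:
    def __init__(self):
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "pool needs even spatial dims"
        self._shape = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        blocks = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return blocks.reshape(n, c, h, w)


class Upsample2x:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_softmax_ce(
    logits: np.ndarray, target: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-pixel categorical cross-entropy with class weights.

    ``logits``: (N, K, H, W); ``target``: (N, H, W) int labels;
    ``class_weights``: (K,).  Loss is the weighted mean of -log p(target);
    returns ``(loss, dlogits)``.
    """
    n, k, h, w = logits.shape
    p = softmax(logits, axis=1)
    onehot = np.zeros_like(p)
    idx0, idx2, idx3 = np.ogrid[:n, :h, :w]
    onehot[idx0, target, idx2, idx3] = 1.0
    wpix = class_weights[target]  # (N, H, W)
    denom = float(wpix.sum())
    if denom == 0:
        return 0.0, np.zeros_like(logits)
    p_true = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    loss = float((wpix * -np.log(np.clip(p_true, 1e-12, None))).sum() / denom)
    dlogits = (p - onehot) * wpix[:, None] / denom
    return loss, dlogits


class Adam:
    """Adam over a flat list of (layer, param-name) pairs."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.entries = [
            (lay, name) for lay in layers if hasattr(lay, "params")
            for name in lay.params
        ]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(lay.params[name]) for lay, name in self.entries]
        self.v = [np.zeros_like(lay.params[name]) for lay, name in self.entries]

    def zero_grad(self):
        for lay, name in self.entries:
            lay.grads[name][...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (lay, name) in enumerate(self.entries):
            g = lay.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            lay.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
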