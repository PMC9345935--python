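"""Minimal NumPy layers for the encoder-decoder pixel classifier.

Data layout is NHWC throughout; convolutions are 3x3, stride 1, zero-padded
("same"). Each layer caches what its backward pass needs; parameters are
exposed as dicts ``{"w": array, "dw": array, "v": array}`` (value, gradient,
momentum buffer) so the SGD loop can update them uniformly.
"""

from __future__ import annotations

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class Conv3x3:
    """3x3 same-size convolution, He-initialized; im2col + one matmul.

    Borders are reflect-padded (not zero-padded) so that tile-border
    statistics match the package-wide reflection convention of the tiled
    inference scheme; this keeps models trained on small patches consistent
    with inference on large context tiles.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (9 * cin))
        self.w = rng.normal(0.0, std, size=(3, 3, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.params = [
            {"w": self.w, "dw": np.zeros_like(self.w), "v": np.zeros_like(self.w)},
            {"w": self.b, "dw": np.zeros_like(self.b), "v": np.zeros_like(self.b)},
        ]
        self._cols = None
        self._shape = None

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="reflect")
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        # (n, h, w, c, 3, 3) -> rows of (ky, kx, c) to match self.w's layout
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, 9 * c
        )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, c = x.shape
        cols = self._im2col(x)
        out = cols @ self.w.reshape(9 * c, -1)
        out += self.b
        if training:
            self._cols = cols
            self._shape = (n, h, w, c)
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        cout = self.w.shape[3]
        dmat = dout.reshape(n * h * w, cout)
        self.params[0]["dw"][...] = (self._cols.T @ dmat).reshape(self.w.shape)
        self.params[1]["dw"][...] = dmat.sum(axis=0)
        dcols = (dmat @ self.w.reshape(9 * c, cout).T).reshape(n, h, w, 3, 3, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        for ky in range(3):
            for kx in range(3):
                dxp[:, ky : ky + h, kx : kx + w, :] += dcols[:, :, :, ky, kx, :]
        # fold gradients at reflect-padded positions back onto their sources
        dxp[:, 2, :, :] += dxp[:, 0, :, :]
        dxp[:, h - 1, :, :] += dxp[:, h + 1, :, :]
        dxp[:, :, 2, :] += dxp[:, :, 0, :]
        dxp[:, :, w - 1, :] += dxp[:, :, w + 1, :]
        self._cols = None
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class BatchNorm:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.params = [
            {"w": self.gamma, "dw": np.zeros_like(self.gamma), "v": np.zeros_like(self.gamma)},
            {"w": self.beta, "dw": np.zeros_like(self.beta), "v": np.zeros_like(self.beta)},
        ]
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean[...] = (
                _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mean
            )
            self.running_var[...] = (
                _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var
            )
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean) * invstd
        if training:
            self._cache = (xhat, invstd.astype(np.float32))
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self._cache = None
        m = float(dout.shape[0] * dout.shape[1] * dout.shape[2])
        self.params[0]["dw"][...] = (dout * xhat).sum(axis=(0, 1, 2))
        self.params[1]["dw"][...] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma
        return (
            invstd
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 1, 2))
                - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
            )
        ).astype(np.float32)


class ReLU:
    def __init__(self):
        self.params = []
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = dout * self._mask
        self._mask = None
        return out


def max_pool_2x2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling; returns (pooled, argmax index in 0..3 per window)."""
    n, h, w, c = x.shape
    win = (
        x.reshape(n, h // 2, 2, w // 2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h // 2, w // 2, c, 4)
    )
    idx = win.argmax(axis=-1)
    pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return pooled, idx.astype(np.int8)


def max_unpool_2x2(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Place each value at the position its paired pooling recorded."""
    n, h2, w2, c = x.shape
    win = np.zeros((n, h2, w2, c, 4), dtype=x.dtype)
    np.put_along_axis(win, idx[..., None].astype(np.int64), x[..., None], axis=-1)
    return (
        win.reshape(n, h2, w2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h2 * 2, w2 * 2, c)
    )


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray, weights=None) -> float:
    """Mean per-pixel categorical cross-entropy, -log p at the true class.

    ``probs`` is (..., K) softmax output, ``labels`` integer classes of the
    matching leading shape. Optional per-class weights reweight pixels.
    """
    p = np.take_along_axis(probs, labels[..., None].astype(np.int64), axis=-1)[..., 0]
    nll = -np.log(np.maximum(p, 1e-12))
    if weights is None:
        return float(nll.mean())
    wpix = np.asarray(weights)[labels]
    return float((nll * wpix).sum() / wpix.sum())
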