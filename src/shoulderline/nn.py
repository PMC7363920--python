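"""A small, self-contained convolutional network trainer (numpy, CPU).

The orientation estimator needs only a compact CNN: a few stride-2 3x3
convolution blocks, a dense head and a soft-max output over orientation bins,
trained with cross-entropy against soft (two-hot) targets.  This module
implements exactly that — forward, backward and an Adam optimizer — in
float32 numpy, with convolutions phrased as im2col matrix products so the
heavy lifting happens in BLAS.  Everything is deterministic given the seed
(single generator, no global state).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SmallCNN", "TrainingDivergedError"]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N*oh*ow, C*k*k) patch matrix."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    # -> (N, oh, ow, C*k*k) -> 2-D
    return cols.transpose(0, 4, 5, 1, 2, 3).reshape(n * oh * ow, c * k * k)


def _col2im(dcols: np.ndarray, shape, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back onto the input."""
    n, c, hp, wp = shape
    dxp = np.zeros(shape, dtype=dcols.dtype)
    d6 = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d6[:, :, i, j]
    return dxp


@dataclass
class _ConvSpec:
    channels: int
    kernel: int
    stride: int


class SmallCNN:
    """Sequential CNN: conv(+ReLU) blocks, flatten or global-average pool,
    dense(+ReLU) layers, final dense + soft-max over ``bin_count`` outputs.

    ``conv_blocks`` is a list of (channels, kernel, stride); padding is
    kernel//2 ('same' before striding).  Weights use He initialization from
    the supplied generator.
    """

    def __init__(
        self,
        input_size: int,
        conv_blocks: list[tuple[int, int, int]],
        dense_widths: list[int],
        bin_count: int,
        rng: np.random.Generator,
        pool: str = "flatten",
    ):
        if pool not in ("flatten", "gap"):
            raise ValueError("pool must be 'flatten' or 'gap'")
        self.input_size = input_size
        self.conv = [_ConvSpec(*b) for b in conv_blocks]
        self.pool = pool
        self.bin_count = bin_count
        self.params: list[np.ndarray] = []
        self._conv_w: list[int] = []  # indices into params
        c_in, hw = 1, input_size
        for spec in self.conv:
            fan_in = c_in * spec.kernel * spec.kernel
            w = rng.normal(0, np.sqrt(2.0 / fan_in), (spec.channels, fan_in)).astype(np.float32)
            b = np.zeros(spec.channels, dtype=np.float32)
            self._conv_w.append(len(self.params))
            self.params += [w, b]
            pad = spec.kernel // 2
            hw = (hw + 2 * pad - spec.kernel) // spec.stride + 1
            c_in = spec.channels
        self._feat_hw = hw
        width = c_in if pool == "gap" else c_in * hw * hw
        self._dense_w: list[int] = []
        for dw in list(dense_widths) + [bin_count]:
            w = rng.normal(0, np.sqrt(2.0 / width), (width, dw)).astype(np.float32)
            b = np.zeros(dw, dtype=np.float32)
            self._dense_w.append(len(self.params))
            self.params += [w, b]
            width = dw

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (N, H, W) normalized imagelets -> (N, B) soft-max probabilities."""
        n = x.shape[0]
        a = x.astype(np.float32).reshape(n, 1, self.input_size, self.input_size)
        cache = {"conv": [], "x_shape": a.shape}
        for li, spec in enumerate(self.conv):
            w, b = self.params[self._conv_w[li]], self.params[self._conv_w[li] + 1]
            pad = spec.kernel // 2
            hp = a.shape[2] + 2 * pad
            oh = (hp - spec.kernel) // spec.stride + 1
            xp = np.pad(a, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            cols = _im2col(xp, spec.kernel, spec.stride, oh, oh)
            z = cols @ w.T + b
            relu_mask = z > 0
            z *= relu_mask
            if want_cache:
                cache["conv"].append((cols, relu_mask, xp.shape, oh))
            a = z.reshape(n, oh, oh, spec.channels).transpose(0, 3, 1, 2)
        if self.pool == "gap":
            feat = a.mean(axis=(2, 3))
        else:
            feat = a.reshape(n, -1)
        cache["feat_in_shape"] = a.shape
        acts = [feat]
        h = feat
        relus = []
        for di, base in enumerate(self._dense_w):
            w, b = self.params[base], self.params[base + 1]
            h = h @ w + b
            if di < len(self._dense_w) - 1:
                mask = h > 0
                h *= mask
                relus.append(mask)
            acts.append(h)
        cache["dense_acts"] = acts
        cache["dense_relus"] = relus
        logits = h - h.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return (p, cache) if want_cache else p

    def loss_and_grads(self, x: np.ndarray, targets: np.ndarray):
        """Mean cross-entropy against soft targets and grads for all params."""
        p, cache = self.forward(x, want_cache=True)
        n = x.shape[0]
        loss = float(-np.sum(targets * np.log(np.maximum(p, 1e-12))) / n)
        grads = [np.zeros_like(q) for q in self.params]
        dz = (p - targets.astype(np.float32)) / np.float32(n)
        # dense stack backward
        h_grad = dz
        for di in range(len(self._dense_w) - 1, -1, -1):
            base = self._dense_w[di]
            w = self.params[base]
            a_in = cache["dense_acts"][di]
            grads[base] = a_in.T @ h_grad
            grads[base + 1] = h_grad.sum(axis=0)
            h_grad = h_grad @ w.T
            if di > 0:
                h_grad *= cache["dense_relus"][di - 1]
        # un-pool
        a_shape = cache["feat_in_shape"]
        if self.pool == "gap":
            da = np.broadcast_to(
                (h_grad / (a_shape[2] * a_shape[3]))[:, :, None, None], a_shape
            ).astype(np.float32)
        else:
            da = h_grad.reshape(a_shape)
        # conv stack backward
        for li in range(len(self.conv) - 1, -1, -1):
            spec = self.conv[li]
            base = self._conv_w[li]
            w = self.params[base]
            cols, relu_mask, xp_shape, oh = cache["conv"][li]
            dz2 = da.transpose(0, 2, 3, 1).reshape(-1, spec.channels)
            dz2 = dz2 * relu_mask.astype(np.float32)
            grads[base] = dz2.T @ cols
            grads[base + 1] = dz2.sum(axis=0)
            dcols = dz2 @ w
            dxp = _col2im(dcols, xp_shape, spec.kernel, spec.stride, oh, oh)
            pad = spec.kernel // 2
            da = dxp[:, :, pad : xp_shape[2] - pad, pad : xp_shape[3] - pad] if pad else dxp
        return loss, grads


class Adam:
    """Adaptive-moment gradient descent with bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
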