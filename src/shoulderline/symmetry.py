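"""O(2) transforms of imagelets and the group-averaged estimator.

A rigid rotation of a pedestrian by ``alpha`` adds ``alpha`` to their
orientation; mirroring about ``e_y`` negates it.  Any orientation estimator
``f`` should therefore be covariant: ``f(phi I) = (f(I) + alpha) * det(phi)``
for every ``phi = Phi R_alpha`` in O(2).  Training-time augmentation makes
``f`` approximately covariant; this module builds the *strictly* equivariant
estimator by averaging ``f`` over a sampled subset of the group:
each sampled rotation is evaluated both with and without the flip (2k network
evaluations for k rotations), each evaluation is mapped back to an estimate of
the original orientation, and the estimates are combined with the P1 circular
mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .circular import RESULTANT_TOL, DegenerateDistributionError, wrap_p1
from .synthgen import Imagelet

logger = logging.getLogger(__name__)

__all__ = [
    "PlaneTransform",
    "GroupAverageConfig",
    "rotate_batch",
    "transform_imagelet",
    "group_average",
    "group_average_batch",
]


@dataclass(frozen=True)
class PlaneTransform:
    """An element of O(2): rotation by ``alpha`` optionally followed by the
    reflection about the e_y direction (a left-right mirror of the imagelet)."""

    alpha: float = 0.0
    flip: bool = False

    @property
    def det(self) -> int:
        return -1 if self.flip else 1

    def compose(self, other: "PlaneTransform") -> "PlaneTransform":
        """self after other (matrix product Phi_s R_s Phi_o R_o)."""
        # J R_a = R_{-a} J  =>  (Phi1 R_a)(Phi2 R_b) = Phi1 Phi2 R_{det2 * a + b}
        return PlaneTransform(
            alpha=self.alpha * other.det + other.alpha, flip=self.flip ^ other.flip
        )

    def apply_angle(self, theta: float) -> float:
        """Covariant action on an orientation: theta -> det * (theta + alpha)."""
        return wrap_p1(self.det * (theta + self.alpha))


@dataclass(frozen=True)
class GroupAverageConfig:
    """How many O(2) samples to average over and how to draw them."""

    k: int = 8
    sampling: str = "uniform"  # "uniform" grid alpha_j = 2*pi*j/k, or "random"
    rng_seed: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.sampling not in ("uniform", "random"):
            raise ValueError("sampling must be 'uniform' or 'random'")


def rotate_batch(pixels: np.ndarray, alphas, fill: float) -> np.ndarray:
    """Rotate each (H, W) imagelet in a (N, H, W) stack about its center.

    Content rotates counterclockwise in the x-y frame (x = columns rightward,
    y = rows upward) by its own angle; bilinear interpolation, out-of-bounds
    samples take the ``fill`` (background) value.
    """
    pixels = np.asarray(pixels)
    n, h, w = pixels.shape
    if h != w:
        raise ValueError("imagelets must be square")
    alphas = np.broadcast_to(np.asarray(alphas, dtype=float), (n,))
    c = (h - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    x = cols - c
    y = c - rows
    ca = np.cos(alphas)[:, None, None]
    sa = np.sin(alphas)[:, None, None]
    # inverse map: source point = R_{-alpha} (x, y)
    xs = ca * x + sa * y
    ys = -sa * x + ca * y
    sc = xs + c  # source column
    sr = c - ys  # source row
    c0 = np.floor(sc).astype(np.int64)
    r0 = np.floor(sr).astype(np.int64)
    fc = (sc - c0).astype(pixels.dtype if pixels.dtype.kind == "f" else np.float64)
    fr = (sr - r0).astype(fc.dtype)
    out = np.empty_like(pixels, dtype=fc.dtype)
    acc = np.zeros((n, h, w), dtype=fc.dtype)
    batch_idx = np.broadcast_to(np.arange(n)[:, None, None], (n, h, w))
    for dr, dc, wgt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr, cc = r0 + dr, c0 + dc
        inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        vals = np.where(inside, pixels[batch_idx, np.clip(rr, 0, h - 1), np.clip(cc, 0, w - 1)], fill)
        acc += wgt * vals
    out[:] = acc
    return out


def flip_batch(pixels: np.ndarray) -> np.ndarray:
    """Mirror each imagelet about the e_y direction (exact column reversal)."""
    return pixels[..., ::-1]


def transform_imagelet(img: Imagelet, t: PlaneTransform) -> Imagelet:
    """Apply an O(2) element: rotate about the center, then optionally flip.

    The ground truth transforms covariantly: ``theta -> det * (theta + alpha)``.
    The identity returns bit-identical pixels; the pure flip is an exact pixel
    mirror (the grid is symmetric about its center).
    """
    px = img.pixels[None]
    if t.alpha != 0.0:
        px = rotate_batch(px, t.alpha, img.background_depth_mm)
        px = np.minimum(px, img.background_depth_mm)
    if t.flip:
        px = flip_batch(px)
    return Imagelet(
        np.ascontiguousarray(px[0], dtype=np.float32),
        img.background_depth_mm,
        img.pixel_pitch_m,
    )


def _sample_alphas(cfg: GroupAverageConfig, rng: np.random.Generator | None) -> np.ndarray:
    if cfg.sampling == "uniform":
        return 2 * np.pi * np.arange(cfg.k) / cfg.k
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    return rng.uniform(0, 2 * np.pi, cfg.k)


def group_average(predict_fn, img: Imagelet, cfg: GroupAverageConfig) -> float:
    """O(2) group-averaged orientation estimate for a single imagelet.

    ``predict_fn`` maps an Imagelet to a P1 angle.  For each sampled rotation
    ``alpha_j`` the imagelet is evaluated rotated (estimate
    ``wrap(f(R_a I) - a)``) and rotated-then-flipped (estimate
    ``wrap(-f(J R_a I) - a)``); the 2k estimates are combined with the P1
    circular mean.  A near-zero resultant means the estimates are incoherent
    (e.g. a constant estimator, whose flip-antisymmetrized average vanishes)
    and raises :class:`DegenerateDistributionError`.
    """
    from .circular import mean_p1_angles

    alphas = _sample_alphas(cfg, None)
    estimates = []
    for a in alphas:
        rot = transform_imagelet(img, PlaneTransform(alpha=a))
        estimates.append(wrap_p1(predict_fn(rot) - a))
        flipped = transform_imagelet(rot, PlaneTransform(flip=True))
        estimates.append(wrap_p1(-predict_fn(flipped) - a))
    return mean_p1_angles(np.asarray(estimates))


def group_average_batch(
    predict_batch_fn,
    pixels: np.ndarray,
    background_mm: float,
    cfg: GroupAverageConfig,
    training_bias_deg: float | None = None,
) -> np.ndarray:
    """Vectorized group average over a (N, H, W) imagelet stack.

    ``predict_batch_fn`` maps a pixel stack to a (N,) array of P1 angles.
    Evaluates 2k predictions per imagelet (each sampled rotation with and
    without flip) and returns the per-imagelet P1 circular mean of the
    back-mapped estimates.  Degenerate imagelets yield NaN (warned).  If the
    estimator carries a recorded training bias above 1 degree a warning is
    emitted: plain group averaging assumes a bias-free estimator.
    """
    if training_bias_deg is not None and abs(training_bias_deg) > 1.0:
        warnings.warn(
            f"estimator training bias {training_bias_deg:.2f} deg exceeds 1 deg; "
            "group averaging assumes a bias-free estimator"
        )
    rng = np.random.default_rng(cfg.rng_seed)
    n = pixels.shape[0]
    sx = np.zeros(n)
    sy = np.zeros(n)
    for j in range(cfg.k):
        if cfg.sampling == "uniform":
            alphas = np.full(n, 2 * np.pi * j / cfg.k)
        else:
            alphas = rng.uniform(0, 2 * np.pi, n)
        rot = rotate_batch(pixels, alphas, background_mm)
        np.minimum(rot, background_mm, out=rot)
        e1 = wrap_p1(predict_batch_fn(rot) - alphas)
        e2 = wrap_p1(-predict_batch_fn(flip_batch(rot)) - alphas)
        sx += np.cos(2 * e1) + np.cos(2 * e2)
        sy += np.sin(2 * e1) + np.sin(2 * e2)
    r = np.hypot(sx, sy) / (2 * cfg.k)
    out = wrap_p1(0.5 * np.arctan2(sy, sx))
    bad = r < RESULTANT_TOL
    if np.any(bad):
        warnings.warn(f"group average degenerate on {int(bad.sum())} imagelets")
        out = np.where(bad, np.nan, out)
    return out
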