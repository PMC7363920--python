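"""Arithmetic and statistics on the real projective line P1(R).

Pedestrian shoulder-line orientation is an *axial* quantity: rotating a body
by 180 degrees leaves the shoulder line unchanged, so orientations live on
P1(R), the circle with antipodal points identified.  Every angle here is kept
in radians with the canonical representative in ``(-pi/2, pi/2]`` (so
``-pi/2 == +pi/2`` and ``+pi/2`` is the stored representative of the wrap
point).

The module also provides the *two-hot* encoding used as the training target of
the orientation network — an angle represented as a probability distribution
with mass on at most two adjacent bins — and its inverse, the P1 circular
mean, computed with the standard axial-statistics double-angle construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AngularDistribution",
    "DegenerateDistributionError",
    "DEFAULT_BIN_COUNT",
    "wrap_p1",
    "p1_signed_diff",
    "bin_centers",
    "two_hot_encode",
    "circular_mean_p1",
    "cross_entropy",
]

#: Default number of orientation bins (4 degrees wide each).
DEFAULT_BIN_COUNT = 45

#: Resultant lengths below this are treated as degenerate (no defined mean).
RESULTANT_TOL = 1e-8

#: Clamp for log arguments in the cross-entropy, keeps the loss finite.
EPS_LOG = 1e-12


class DegenerateDistributionError(ValueError):
    """Raised when an angular distribution has no well-defined P1 mean."""


def wrap_p1(angle):
    """Wrap an angle (radians) to the canonical P1 interval ``(-pi/2, pi/2]``.

    Accepts scalars or arrays; NaN/inf raise ``ValueError``.
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_p1 requires finite input")
    # shift so the target interval maps to [0, pi), then shift back
    wrapped = np.pi / 2 - np.mod(np.pi / 2 - a, np.pi)
    # np.mod returns values in [0, pi); value 0 corresponds to +pi/2 exactly
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def p1_signed_diff(a, b):
    """Signed projective difference ``a - b`` wrapped to ``(-pi/2, pi/2]``.

    The result is the shortest signed arc from ``b`` to ``a`` on P1:
    ``wrap_p1(b + p1_signed_diff(a, b)) == wrap_p1(a)``.
    """
    return wrap_p1(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class AngularDistribution:
    """Discrete probability distribution over ``bin_count`` uniform P1 bins.

    Bin ``i`` covers ``[-pi/2 + i*w, -pi/2 + (i+1)*w)`` with ``w = pi/B``;
    its center sits at the interval midpoint.  Used both for the network's
    soft-max output and the two-hot training targets.
    """

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("weights must be a 1-D array with >= 2 bins")
        if np.any(w < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        object.__setattr__(self, "weights", w)

    @property
    def bin_count(self) -> int:
        return self.weights.size

    @property
    def bin_width(self) -> float:
        return np.pi / self.bin_count

    @property
    def bin_centers(self) -> np.ndarray:
        return bin_centers(self.bin_count)


def bin_centers(B: int) -> np.ndarray:
    """Centers of the B uniform P1 bins, each wrapped to the canonical interval."""
    if B < 2:
        raise ValueError("bin count must be >= 2")
    w = np.pi / B
    return -np.pi / 2 + (np.arange(B) + 0.5) * w


def two_hot_encode(theta, B: int = DEFAULT_BIN_COUNT) -> AngularDistribution:
    """Encode an orientation as a two-hot distribution over ``B`` bins.

    The weight splits between the two bin centers nearest to ``theta`` (cyclic
    across the wrap point) with linear-interpolation coefficients, so the
    encoding is exactly inverted by :func:`circular_mean_p1` — no quantization
    error.
    """
    if B < 2:
        raise ValueError("bin count must be >= 2")
    weights = two_hot_weights(np.atleast_1d(np.asarray(theta, dtype=float)), B)
    if weights.shape[0] != 1:
        raise ValueError("two_hot_encode takes a scalar angle; see two_hot_weights")
    return AngularDistribution(weights[0])


def two_hot_weights(theta: np.ndarray, B: int = DEFAULT_BIN_COUNT) -> np.ndarray:
    """Vectorized two-hot encoding: (n,) angles -> (n, B) weight rows.

    The split between the two neighboring centers uses sine-corrected
    interpolation coefficients, ``w_upper = sin(2*d1) / (sin(2*d1) +
    sin(2*d2))`` with ``d1, d2`` the angular distances to the lower/upper
    center.  These agree with linear interpolation to second order in the bin
    width but are *exactly* inverted by the double-angle circular mean, so
    the encoding is quantization-free rather than approximately so.
    """
    if B < 2:
        raise ValueError("bin count must be >= 2")
    th = wrap_p1(np.atleast_1d(np.asarray(theta, dtype=float)))
    w = np.pi / B
    # continuous bin coordinate: bin centers sit at u = 0.5, 1.5, ...
    u = (th + np.pi / 2) / w - 0.5
    lo = np.floor(u).astype(int)
    frac = u - lo
    s1 = np.sin(2 * w * frac)
    s2 = np.sin(2 * w * (1.0 - frac))
    upper = np.where(s1 + s2 > 0, s1 / np.where(s1 + s2 > 0, s1 + s2, 1.0), frac)
    out = np.zeros((th.size, B))
    rows = np.arange(th.size)
    out[rows, np.mod(lo, B)] = 1.0 - upper
    np.add.at(out, (rows, np.mod(lo + 1, B)), upper)
    return out


def circular_mean_p1(dist) -> float:
    """P1 circular mean of an angular distribution (double-angle construction).

    Each bin center ``c`` is mapped to the full circle via ``2c``; the weighted
    unit-vector mean is formed there, its angle halved and wrapped back to P1.
    A near-zero resultant (e.g. the uniform distribution) has no meaningful
    mean and raises :class:`DegenerateDistributionError`.
    """
    if isinstance(dist, AngularDistribution):
        weights, centers = dist.weights, dist.bin_centers
    else:
        weights = np.asarray(dist, dtype=float)
        centers = bin_centers(weights.size)
    doubled = 2.0 * centers
    x = float(np.dot(weights, np.cos(doubled)))
    y = float(np.dot(weights, np.sin(doubled)))
    r = np.hypot(x, y)
    if r < RESULTANT_TOL:
        raise DegenerateDistributionError(
            f"resultant length {r:.3g} below {RESULTANT_TOL}: no defined P1 mean"
        )
    return wrap_p1(0.5 * np.arctan2(y, x))


def circular_mean_p1_batch(weight_rows: np.ndarray) -> np.ndarray:
    """Row-wise P1 circular mean of (n, B) weight rows; degenerate rows -> NaN."""
    weight_rows = np.asarray(weight_rows, dtype=float)
    doubled = 2.0 * bin_centers(weight_rows.shape[1])
    x = weight_rows @ np.cos(doubled)
    y = weight_rows @ np.sin(doubled)
    r = np.hypot(x, y)
    out = wrap_p1(0.5 * np.arctan2(y, x))
    out = np.where(r < RESULTANT_TOL, np.nan, out)
    return out


def mean_p1_angles(angles, weights=None) -> float:
    """P1 circular mean of a set of angles (not binned), double-angle trick."""
    a = np.asarray(angles, dtype=float)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    x = float(np.dot(w, np.cos(2 * a)))
    y = float(np.dot(w, np.sin(2 * a)))
    if np.hypot(x, y) < RESULTANT_TOL:
        raise DegenerateDistributionError("angle set has no defined P1 mean")
    return wrap_p1(0.5 * np.arctan2(y, x))


def cross_entropy(pred, target) -> float:
    """Cross-entropy H(pred, target) = -sum target_i log pred_i (nats).

    ``pred`` is clamped at 1e-12 so the loss stays finite when a supported bin
    received zero predicted mass.
    """
    p = pred.weights if isinstance(pred, AngularDistribution) else np.asarray(pred, float)
    t = target.weights if isinstance(target, AngularDistribution) else np.asarray(target, float)
    if p.shape != t.shape:
        raise ValueError("pred and target must have the same bin count")
    return float(-np.dot(t, np.log(np.maximum(p, EPS_LOG))))
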