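"""Synthetic overhead depth imagelets and orientation signals.

An overhead depth view of a walking pedestrian is emulated as the
superposition of two ellipses: an elongated body/shoulder ellipse and a
smaller head ellipse at lower depth (the head is closer to the ceiling-mounted
sensor).  The rotation of the body ellipse *is* the ground-truth orientation,
which makes these imagelets a validation substrate on which the error of any
estimator can be measured exactly.

Conventions (image frame): x runs along columns to the right, y along rows
upward (row 0 is the largest y); orientation angles are measured from +y,
counterclockwise positive, and are pi-periodic.  The body ellipse's *major*
axis lies along the shoulder line, i.e. perpendicular to the orientation
angle's reference direction, so the direction of the major axis measured from
+x equals the orientation angle theta.

Depth values are millimetres from the sensor: smaller = closer = higher above
the floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .circular import wrap_p1
from .dynamics import OrientationSignal

logger = logging.getLogger(__name__)

__all__ = [
    "Imagelet",
    "EllipsePairRanges",
    "SyntheticSample",
    "generate_imagelet",
    "generate_dataset",
    "generate_imagelet_batch",
    "generate_orientation_signal",
    "moment_orientation",
    "DriftSpec",
]


@dataclass(frozen=True)
class Imagelet:
    """Square single-channel depth grid centered on one pedestrian."""

    pixels: np.ndarray  # (H, H) depth in millimetres
    background_depth_mm: float
    pixel_pitch_m: float

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("imagelet must be a square 2-D grid")
        if np.any(px > self.background_depth_mm + 1e-6):
            raise ValueError("pixel depths must not exceed the background depth")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class EllipsePairRanges:
    """Sampling ranges for the body and head ellipses (metres / millimetres).

    Defaults are plausible adult anthropometrics seen from above; the exact
    values are immaterial for validation because the ground truth is known by
    construction.
    """

    body_semi_major_m: tuple[float, float] = (0.20, 0.28)
    body_semi_minor_m: tuple[float, float] = (0.10, 0.16)
    head_semi_axis_m: tuple[float, float] = (0.07, 0.11)
    head_offset_max_m: float = 0.06
    body_drop_mm: tuple[float, float] = (1000.0, 1400.0)
    head_extra_drop_mm: tuple[float, float] = (200.0, 300.0)
    noise_sd_mm: float = 10.0
    dropout_fraction: float = 0.01

    def noiseless(self) -> "EllipsePairRanges":
        return replace(self, noise_sd_mm=0.0, dropout_fraction=0.0, head_offset_max_m=0.0)


DEFAULT_SIZE = 64
DEFAULT_PITCH_M = 0.02
DEFAULT_BACKGROUND_MM = 2600.0


@dataclass(frozen=True)
class SyntheticSample:
    """One imagelet with its ground-truth orientation and (noisy) label."""

    imagelet: Imagelet
    theta_gt: float  # radians, canonical P1 representative
    theta_label: float  # wrap(theta_gt + eps), the training label
    noise_sd_deg: float


#: Sub-pixel supersampling factor for area-coverage rasterization.  A depth
#: pixel integrates over its footprint, so edge pixels take fractional
#: coverage values; this also keeps image-moment orientations accurate.
SUPERSAMPLE = 3


def _grid(size: int, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates (metres) with the origin at the image center."""
    c = (size - 1) / 2.0
    x = (np.arange(size) - c) * pitch  # columns -> +x rightward
    y = (c - np.arange(size)) * pitch  # rows -> +y upward
    return np.meshgrid(x, y)


def _coverage(mask_fine: np.ndarray, size: int, ss: int) -> np.ndarray:
    """Block-average a (size*ss, size*ss) boolean mask to per-pixel coverage."""
    return mask_fine.reshape(size, ss, size, ss).mean(axis=(1, 3))


def _ellipse_mask(X, Y, cx, cy, a, b, theta) -> np.ndarray:
    """Mask of the ellipse with semi-major a along the direction at angle
    theta from +x (= shoulder line for the body ellipse)."""
    dx, dy = X - cx, Y - cy
    ca, sa = np.cos(theta), np.sin(theta)
    u = dx * ca + dy * sa  # along major axis
    v = -dx * sa + dy * ca  # along minor axis
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_imagelet(
    theta_gt: float,
    rng: np.random.Generator | int | None = None,
    ranges: EllipsePairRanges | None = None,
    size: int = DEFAULT_SIZE,
    pixel_pitch_m: float = DEFAULT_PITCH_M,
    background_mm: float = DEFAULT_BACKGROUND_MM,
    label_noise_sd_deg: float = 0.0,
) -> SyntheticSample:
    """Generate one synthetic pedestrian imagelet with known orientation.

    The body ellipse's major axis is aligned with the shoulder line
    (perpendicular to the reference direction of ``theta_gt``); the head
    ellipse is offset along the body's minor axis (the walking direction) by a
    jitter up to ``head_offset_max_m``.  Gaussian depth noise and a small
    pixel-dropout fraction imitate sensor artifacts.  Fully reproducible from
    the rng/seed.  Ellipses that would exceed the imagelet bounds are
    regenerated with shrunk axes (logged), never clipped silently.
    """
    rng = np.random.default_rng(rng)
    ranges = ranges or EllipsePairRanges()
    theta_gt = wrap_p1(float(theta_gt))
    px, thetas = _generate_batch_pixels(
        np.array([theta_gt]), rng, ranges, size, pixel_pitch_m, background_mm
    )
    eps = np.deg2rad(label_noise_sd_deg) * rng.standard_normal() if label_noise_sd_deg else 0.0
    return SyntheticSample(
        Imagelet(px[0], background_mm, pixel_pitch_m),
        theta_gt,
        wrap_p1(theta_gt + eps),
        label_noise_sd_deg,
    )


def _generate_batch_pixels(
    thetas: np.ndarray,
    rng: np.random.Generator,
    ranges: EllipsePairRanges,
    size: int,
    pitch: float,
    background: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a batch of imagelets; returns (N, size, size) float32 mm."""
    ss = SUPERSAMPLE
    Xf, Yf = _grid(size * ss, pitch / ss)
    half_extent = (size - 1) / 2.0 * pitch
    n = thetas.size
    out = np.empty((n, size, size), dtype=np.float32)
    for i in range(n):
        th = thetas[i]
        a = rng.uniform(*ranges.body_semi_major_m)
        b = rng.uniform(*ranges.body_semi_minor_m)
        if a / b < 1.1:  # keep the orientation identifiable
            b = a / 1.1
        hr = rng.uniform(*ranges.head_semi_axis_m)
        off = (
            rng.uniform(-ranges.head_offset_max_m, ranges.head_offset_max_m)
            if ranges.head_offset_max_m > 0
            else 0.0
        )
        body_drop = rng.uniform(*ranges.body_drop_mm)
        head_drop = rng.uniform(*ranges.head_extra_drop_mm)
        while a >= half_extent or abs(off) + hr >= half_extent:
            logger.info("imagelet ellipse exceeds bounds; shrinking axes")
            a, b, hr, off = 0.8 * a, 0.8 * b, 0.8 * hr, 0.8 * off
        # shoulder line (major axis) at angle th from +x; walking direction
        # (minor axis) at angle th from +y
        body_cov = _coverage(_ellipse_mask(Xf, Yf, 0.0, 0.0, a, b, th), size, ss)
        hx, hy = -off * np.sin(th), off * np.cos(th)  # offset along minor axis
        head_cov = _coverage(_ellipse_mask(Xf, Yf, hx, hy, hr, hr, th), size, ss)
        # the head stands (body_drop + head_drop) above the floor wherever it
        # covers, regardless of the body underneath
        drop = np.maximum(body_drop * body_cov, (body_drop + head_drop) * head_cov)
        img = background - drop
        if ranges.noise_sd_mm > 0:
            img += ranges.noise_sd_mm * rng.standard_normal(img.shape)
            np.minimum(img, background, out=img)
        if ranges.dropout_fraction > 0:
            dropmask = rng.random(img.shape) < ranges.dropout_fraction
            img[dropmask] = background
        out[i] = img.astype(np.float32)
    return out, thetas


def generate_imagelet_batch(
    n: int,
    rng: np.random.Generator | int | None = None,
    ranges: EllipsePairRanges | None = None,
    size: int = DEFAULT_SIZE,
    pixel_pitch_m: float = DEFAULT_PITCH_M,
    background_mm: float = DEFAULT_BACKGROUND_MM,
    noise_sd_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized dataset generation for training-scale use.

    Returns ``(pixels, theta_gt, theta_label)`` with pixels of shape
    (n, size, size) in mm, ground truths i.i.d. uniform on P1 and labels
    carrying centered Gaussian noise of ``noise_sd_deg`` (wrapped).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    ranges = ranges or EllipsePairRanges()
    thetas = wrap_p1(rng.uniform(-np.pi / 2, np.pi / 2, size=n))
    px, _ = _generate_batch_pixels(thetas, rng, ranges, size, pixel_pitch_m, background_mm)
    eps = np.deg2rad(noise_sd_deg) * rng.standard_normal(n) if noise_sd_deg > 0 else 0.0
    labels = wrap_p1(thetas + eps)
    return px, thetas, labels


def generate_dataset(
    n: int,
    noise_sd_deg: float = 20.0,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> list[SyntheticSample]:
    """Generate ``n`` samples with uniform-P1 ground truth and noisy labels."""
    rng = np.random.default_rng(rng)
    size = kwargs.get("size", DEFAULT_SIZE)
    pitch = kwargs.get("pixel_pitch_m", DEFAULT_PITCH_M)
    background = kwargs.get("background_mm", DEFAULT_BACKGROUND_MM)
    px, gt, labels = generate_imagelet_batch(
        n, rng, kwargs.get("ranges"), size, pitch, background, noise_sd_deg
    )
    return [
        SyntheticSample(Imagelet(px[i], background, pitch), float(gt[i]), float(labels[i]), noise_sd_deg)
        for i in range(n)
    ]


def moment_orientation(imagelet: Imagelet) -> float:
    """Principal-axis orientation of the above-floor mass (image-moment oracle).

    Returns the direction of the weighted second-moment major axis measured
    from +x, which for a noise-free body ellipse equals the ground-truth
    orientation theta.  Independent of any trained estimator; used as an
    oracle in tests and as an exactly O(2)-equivariant reference estimator.
    """
    X, Y = _grid(imagelet.size, imagelet.pixel_pitch_m)
    w = np.maximum(imagelet.background_depth_mm - imagelet.pixels, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("empty imagelet: no mass above the floor")
    cx, cy = (w * X).sum() / total, (w * Y).sum() / total
    dx, dy = X - cx, Y - cy
    mxx = (w * dx * dx).sum() / total
    myy = (w * dy * dy).sum() / total
    mxy = (w * dx * dy).sum() / total
    return wrap_p1(0.5 * np.arctan2(2 * mxy, mxx - myy))


@dataclass(frozen=True)
class DriftSpec:
    """Slow heading meander: Gaussian noise band-passed around ~0.2 Hz.

    Emulates large-scale path curvature, the low-frequency spectral content
    of real orientation signals, as two Gaussian components: a meander
    band-passed around ~0.2 Hz (``sd_deg``, ``band_hz``) and a slower heading
    wander low-passed below ``wander_cutoff_hz`` (``wander_sd_deg``) that
    gives the spectrum its red sub-0.1 Hz tail.  The defaults suit a
    straight-walking (corridor) cohort at normal speed.
    """

    sd_deg: float = 6.0
    band_hz: tuple[float, float] = (0.1, 0.3)
    wander_sd_deg: float = 2.5
    wander_cutoff_hz: float = 0.05


def generate_orientation_signal(
    duration_s: float,
    rate_hz: float = 30.0,
    mean_heading_rad: float = 0.0,
    sway_freq_hz: float = 0.8,
    sway_amp_deg: float = 5.0,
    drift: DriftSpec | None = DriftSpec(),
    rng: np.random.Generator | int | None = None,
) -> OrientationSignal:
    """Synthetic shoulder-orientation signal: gait sway plus slow drift.

    ``theta(t) = mean + sway_amp*sin(2*pi*f*t + phi0) + drift(t)`` with a
    random initial sway phase and a smooth band-limited Gaussian drift.  The
    sway frequency defaults to the stepping frequency of normal walking
    (~0.8 Hz).  The signal is kept unwrapped (continuous lift).
    """
    if sway_amp_deg >= 90.0:
        raise ValueError("sway amplitude must stay below 90 degrees")
    rng = np.random.default_rng(rng)
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    phi0 = rng.uniform(0, 2 * np.pi)
    theta = mean_heading_rad + np.deg2rad(sway_amp_deg) * np.sin(
        2 * np.pi * sway_freq_hz * t + phi0
    )
    if drift is not None and drift.sd_deg > 0:
        from scipy import signal as sps

        # filter a padded white sequence and keep the interior: zero-phase
        # band-pass filters have strong edge transients that would otherwise
        # leave the drift non-stationary at the signal ends
        pad = int(round(3.0 / drift.band_hz[0] * rate_hz))
        white = rng.standard_normal(n + 2 * pad)
        sos = sps.butter(2, drift.band_hz, btype="bandpass", fs=rate_hz, output="sos")
        slow = sps.sosfiltfilt(sos, white)[pad : pad + n]
        sd = slow.std()
        if sd > 0:
            theta = theta + np.deg2rad(drift.sd_deg) * slow / sd
        if drift.wander_sd_deg > 0:
            padw = int(round(3.0 / drift.wander_cutoff_hz * rate_hz))
            whitew = rng.standard_normal(n + 2 * padw)
            sosw = sps.butter(2, drift.wander_cutoff_hz, btype="low", fs=rate_hz, output="sos")
            wander = sps.sosfiltfilt(sosw, whitew)[padw : padw + n]
            sdw = wander.std()
            if sdw > 0:
                theta = theta + np.deg2rad(drift.wander_sd_deg) * wander / sdw
    return OrientationSignal(t, theta, rate_hz)
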