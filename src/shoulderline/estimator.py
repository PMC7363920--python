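"""The CNN orientation point-estimator and its weak-label training loop.

The estimator maps a depth imagelet to a discrete probability distribution
over orientation bins (soft-max output); the point estimate is the P1
circular mean of that distribution.  Training minimizes the cross-entropy
between the predicted distribution and the two-hot encoding of the label.

The labels need not be exact: velocity directions (or synthetic ground truth
plus centered noise) are *weak* labels — individually imperfect but correct
on average.  Because the soft-max/cross-entropy pair makes the output
converge to the conditional label distribution, whose circular mean is the
noise-free orientation, the point estimate self-amends the label noise as the
training set grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .circular import (
    DEFAULT_BIN_COUNT,
    circular_mean_p1_batch,
    two_hot_weights,
    wrap_p1,
)
from .dynamics import Trajectory, velocity_direction
from .symmetry import flip_batch, rotate_batch
from .synthgen import DEFAULT_BACKGROUND_MM, Imagelet

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "TrainingSet",
    "TrainedEstimator",
    "EmptyDatasetError",
    "build_training_set",
    "build_training_set_from_trajectories",
    "augment_batch",
    "train",
    "predict",
]

#: Depth span (mm) used to normalize imagelets to ~[0, 1].
DEFAULT_CONTRAST_MM = 1800.0


class EmptyDatasetError(ValueError):
    """No training samples survived filtering/subsampling."""


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the compact orientation CNN.

    The default (three stride-2 conv blocks, flattened features, one dense
    hidden layer, 45-bin soft-max head) is a desk-scale architecture of about
    0.1 M parameters; the architecture is a configuration choice, not a
    constant of the method.
    """

    imagelet_size: int = 64
    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 3, 2), (32, 3, 2), (64, 3, 2))
    dense_widths: tuple[int, ...] = (128,)
    bin_count: int = DEFAULT_BIN_COUNT
    pool: str = "flatten"


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyper-parameters and real-data filtering constants.

    ``min_speed_mps`` (0.65 m/s) excludes pedestrians whose velocity carries
    no orientation information; ``subsample_dt_s`` (0.5 s) decorrelates
    samples taken from the same trajectory.
    """

    label_source: str = "ground_truth_plus_noise"  # or "velocity_direction"
    augment: bool = True
    epochs: int = 12
    batch_size: int = 128
    learning_rate: float = 1e-3
    rng_seed: int = 0
    min_speed_mps: float = 0.65
    subsample_dt_s: float = 0.5


@dataclass(frozen=True)
class TrainingSet:
    """Imagelets (raw depth, mm) with their weak labels (radians, P1)."""

    pixels_mm: np.ndarray  # (N, H, H) float32
    labels: np.ndarray  # (N,) radians
    background_mm: float = DEFAULT_BACKGROUND_MM

    def __post_init__(self):
        if self.pixels_mm.shape[0] != self.labels.shape[0]:
            raise ValueError("pixels and labels must have equal length")
        if self.pixels_mm.shape[0] == 0:
            raise EmptyDatasetError("training set is empty")

    def __len__(self) -> int:
        return int(self.labels.size)


def build_training_set(
    pixels_mm: np.ndarray,
    labels: np.ndarray,
    background_mm: float = DEFAULT_BACKGROUND_MM,
) -> TrainingSet:
    """Assemble a training set from imagelet pixels and angle labels."""
    return TrainingSet(
        np.asarray(pixels_mm, dtype=np.float32),
        wrap_p1(np.asarray(labels, dtype=float)),
        background_mm,
    )


def build_training_set_from_trajectories(
    records: list[tuple[Trajectory, np.ndarray]],
    cfg: TrainingConfig,
    background_mm: float = DEFAULT_BACKGROUND_MM,
) -> TrainingSet:
    """Velocity-direction weak labels from trajectory + imagelet-stream pairs.

    Each record pairs a 30 Hz trajectory with its per-frame imagelet stack
    (T, H, H).  Trajectories slower on average than ``cfg.min_speed_mps`` are
    dropped; the rest are subsampled every ``cfg.subsample_dt_s`` seconds and
    labeled with the instantaneous velocity direction.
    """
    pixels, labels = [], []
    for traj, frames in records:
        if traj.mean_speed_mps < cfg.min_speed_mps:
            continue
        if frames.shape[0] != traj.t.size:
            raise ValueError("imagelet stream length must match the trajectory")
        sig = velocity_direction(traj)
        step = max(1, int(round(cfg.subsample_dt_s * traj.rate_hz)))
        idx = np.arange(0, traj.t.size, step)
        if sig.low_confidence is not None:
            idx = idx[~sig.low_confidence[idx]]
        pixels.append(frames[idx])
        labels.append(wrap_p1(sig.theta[idx]))
    if not pixels:
        raise EmptyDatasetError(
            f"no trajectory passed the {cfg.min_speed_mps} m/s average-speed filter"
        )
    return build_training_set(np.concatenate(pixels), np.concatenate(labels), background_mm)


def augment_batch(
    pixels_mm: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    background_mm: float = DEFAULT_BACKGROUND_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Random O(2) orbit element per sample: rotation uniform on [0, 2*pi)
    plus a Bernoulli(1/2) left-right flip, applied consistently to imagelets
    and labels (rotation adds alpha, flip negates).  Makes the label
    distribution uniform on P1 regardless of the input distribution.
    """
    n = pixels_mm.shape[0]
    alphas = rng.uniform(0, 2 * np.pi, n)
    flips = rng.random(n) < 0.5
    out = rotate_batch(pixels_mm, alphas, background_mm)
    np.minimum(out, background_mm, out=out)
    out[flips] = flip_batch(out[flips])
    det = np.where(flips, -1.0, 1.0)
    new_labels = wrap_p1(det * (labels + alphas))
    return out, new_labels


def normalize_imagelets(
    pixels_mm: np.ndarray,
    background_mm: float,
    contrast_mm: float = DEFAULT_CONTRAST_MM,
) -> np.ndarray:
    """Depth -> unitless height map: (background - depth) / contrast.

    Zero on the floor, larger for objects nearer the sensor; makes the
    network insensitive to the absolute sensor height.
    """
    return ((background_mm - pixels_mm) / contrast_mm).astype(np.float32)


@dataclass
class TrainedEstimator:
    """A trained orientation network plus its provenance metadata."""

    net: nn.SmallCNN
    net_config: NetworkConfig
    train_config: TrainingConfig
    loss_history: list[float]
    background_mm: float = DEFAULT_BACKGROUND_MM
    contrast_mm: float = DEFAULT_CONTRAST_MM
    metadata: dict = field(default_factory=dict)

    def predict_batch(self, pixels_mm: np.ndarray, chunk: int = 1024):
        """(N, H, H) raw-depth imagelets -> (probs (N, B), theta_o (N,))."""
        pixels_mm = np.asarray(pixels_mm)
        if pixels_mm.shape[1:] != (self.net_config.imagelet_size,) * 2:
            raise ValueError(
                f"imagelet size {pixels_mm.shape[1:]} does not match the "
                f"configured {self.net_config.imagelet_size}"
            )
        x = normalize_imagelets(pixels_mm, self.background_mm, self.contrast_mm)
        probs = np.concatenate(
            [self.net.forward(x[i : i + chunk]) for i in range(0, x.shape[0], chunk)]
        )
        return probs, circular_mean_p1_batch(probs)

    def predict_angles(self, pixels_mm: np.ndarray) -> np.ndarray:
        return self.predict_batch(pixels_mm)[1]


def train(
    train_set: TrainingSet,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainingConfig | None = None,
) -> TrainedEstimator:
    """Train the orientation CNN on weak labels.

    Minimizes the mean cross-entropy between the soft-max output and the
    two-hot encoded labels with Adam.  When ``train_cfg.augment`` is set,
    every epoch draws a fresh random O(2) orbit element per sample.  Fully
    deterministic given ``train_cfg.rng_seed``.  A non-finite loss aborts
    with :class:`nn.TrainingDivergedError`.
    """
    net_cfg = net_cfg or NetworkConfig()
    train_cfg = train_cfg or TrainingConfig()
    if train_set.pixels_mm.shape[1] != net_cfg.imagelet_size:
        raise ValueError("training imagelet size does not match the network config")
    rng = np.random.default_rng(train_cfg.rng_seed)
    net = nn.SmallCNN(
        net_cfg.imagelet_size,
        list(net_cfg.conv_blocks),
        list(net_cfg.dense_widths),
        net_cfg.bin_count,
        rng,
        pool=net_cfg.pool,
    )
    opt = nn.Adam(net.params, lr=train_cfg.learning_rate)
    n = len(train_set)
    history: list[float] = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            px = train_set.pixels_mm[idx]
            lab = train_set.labels[idx]
            if train_cfg.augment:
                px, lab = augment_batch(px, lab, rng, train_set.background_mm)
            x = normalize_imagelets(px, train_set.background_mm)
            targets = two_hot_weights(lab, net_cfg.bin_count)
            loss, grads = net.loss_and_grads(x, targets)
            if not np.isfinite(loss):
                raise nn.TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            opt.step(net.params, grads)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
        logger.info("epoch %d/%d: loss %.4f", epoch + 1, train_cfg.epochs, history[-1])
    return TrainedEstimator(
        net,
        net_cfg,
        train_cfg,
        history,
        train_set.background_mm,
        metadata={"n_train": n, "seed": train_cfg.rng_seed},
    )


def predict(est: TrainedEstimator, imagelet: Imagelet):
    """Point-estimate the orientation of one imagelet.

    Returns ``(h_pred, theta_o)`` where ``theta_o`` is the P1 circular mean
    of the predicted distribution ``h_pred``.
    """
    from .circular import AngularDistribution

    probs, thetas = est.predict_batch(imagelet.pixels[None])
    theta = float(thetas[0])
    if np.isnan(theta):
        from .circular import DegenerateDistributionError

        raise DegenerateDistributionError("predicted distribution has no defined P1 mean")
    p = probs[0].astype(float)
    return AngularDistribution(p / p.sum()), theta
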