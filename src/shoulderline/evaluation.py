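"""Error protocol for replicated estimator evaluations.

Two indicators separate systematic from random error across ``M`` replicate
networks trained on independent datasets:

* aggregate bias ``b_hat``: the root-mean-square of the per-network mean
  residuals (a constant rotation offset shows up here);
* ARMSE: the mean over replicates of the per-network RMS residual, which
  decomposes per replicate as ``sqrt(bias_k**2 + variance_k)``.

Residuals are signed projective differences, confined to (-pi/2, pi/2]; the
plain arithmetic mean is valid there (residuals near the +-pi/2 boundary are
wrap-ambiguous and trigger a warning).  Also provided: learning-curve and
replicated-experiment drivers and the low-pass reference-label builder used
in place of ground truth on real data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import p1_signed_diff
from .dynamics import OrientationSignal, lowpass

logger = logging.getLogger(__name__)

__all__ = [
    "bias",
    "aggregate_bias",
    "armse",
    "EvaluationRun",
    "ReplicateResult",
    "run_bias_experiment",
    "learning_curve",
    "fit_power_law",
    "make_reference_labels",
]

_WRAP_WARN_DEG = 80.0


def _residuals_deg(preds, refs) -> np.ndarray:
    preds = np.asarray(preds, dtype=float)
    refs = np.asarray(refs, dtype=float)
    if preds.shape != refs.shape or preds.ndim != 1 or preds.size < 1:
        raise ValueError("preds and refs must be equal-length 1-D arrays")
    res = np.rad2deg(p1_signed_diff(preds, refs))
    if np.any(np.abs(res) > _WRAP_WARN_DEG):
        warnings.warn(
            "residuals near the +-90 deg boundary: wrap ambiguity may distort the mean"
        )
    return res


def bias(preds, refs) -> float:
    """Mean signed residual (degrees) of predictions against references."""
    return float(np.mean(_residuals_deg(preds, refs)))


def aggregate_bias(per_network_biases) -> float:
    """Root-mean-square of the individual network biases (degrees)."""
    b = np.asarray(per_network_biases, dtype=float)
    if b.size < 1:
        raise ValueError("need at least one replicate bias")
    return float(np.sqrt(np.mean(b**2)))


def armse(per_network_residuals: list[np.ndarray]) -> float:
    """Mean over replicates of the RMS residual (degrees).

    Algebraically identical to averaging ``sqrt(bias_k**2 + variance_k)``.
    """
    if len(per_network_residuals) < 1:
        raise ValueError("need at least one replicate")
    return float(
        np.mean([np.sqrt(np.mean(np.asarray(r, float) ** 2)) for r in per_network_residuals])
    )


@dataclass(frozen=True)
class ReplicateResult:
    """Residuals of one replicate network on the shared test set (degrees)."""

    bias_deg: float
    rmse_deg: float
    residuals_gt_deg: np.ndarray
    residuals_noisy_deg: np.ndarray | None = None
    residuals_ga_deg: np.ndarray | None = None  # with group averaging, vs gt


@dataclass(frozen=True)
class EvaluationRun:
    """Aggregate error indicators of an M-replicate evaluation."""

    n_train: int
    replicates: list[ReplicateResult]
    aggregate_bias_deg: float
    armse_deg: float
    armse_noisy_deg: float | None = None
    aggregate_bias_ga_deg: float | None = None
    armse_ga_deg: float | None = None

    @property
    def M(self) -> int:
        return len(self.replicates)


def run_bias_experiment(
    n_train: int,
    m_replicates: int,
    seed: int,
    n_test: int = 5000,
    noise_sd_deg: float = 20.0,
    imagelet_size: int = 32,
    pixel_pitch_m: float = 0.04,
    net_cfg=None,
    train_cfg=None,
    group_average_k: int = 8,
) -> EvaluationRun:
    """Train M replicate networks on independent synthetic datasets and
    evaluate on a shared held-out set.

    Labels carry centered Gaussian noise of ``noise_sd_deg``; evaluation uses
    noise-free ground truth (and, separately, the noisy labels of the test
    set, to exhibit the label-noise floor).  When ``group_average_k`` is set,
    predictions are additionally made with uniform O(2) group averaging.
    """
    from . import estimator as est_mod
    from . import synthgen
    from .symmetry import GroupAverageConfig, group_average_batch

    root = np.random.SeedSequence(seed)
    test_seed, *train_seeds = root.spawn(m_replicates + 1)
    test_px, test_gt, test_noisy = synthgen.generate_imagelet_batch(
        n_test,
        np.random.default_rng(test_seed),
        size=imagelet_size,
        pixel_pitch_m=pixel_pitch_m,
        noise_sd_deg=noise_sd_deg,
    )
    net_cfg = net_cfg or est_mod.NetworkConfig(imagelet_size=imagelet_size)
    replicates = []
    for k, ts in enumerate(train_seeds):
        rng = np.random.default_rng(ts)
        px, gt, labels = synthgen.generate_imagelet_batch(
            n_train,
            rng,
            size=imagelet_size,
            pixel_pitch_m=pixel_pitch_m,
            noise_sd_deg=noise_sd_deg,
        )
        tset = est_mod.build_training_set(px, labels)
        cfg = train_cfg or est_mod.TrainingConfig()
        cfg = type(cfg)(**{**cfg.__dict__, "rng_seed": int(rng.integers(2**31))})
        trained = est_mod.train(tset, net_cfg, cfg)
        _, preds = trained.predict_batch(test_px)
        res_gt = _residuals_deg(preds, test_gt)
        res_noisy = _residuals_deg(preds, test_noisy)
        res_ga = None
        if group_average_k:
            ga_cfg = GroupAverageConfig(k=group_average_k, sampling="uniform")
            preds_ga = group_average_batch(
                trained.predict_angles, test_px, trained.background_mm, ga_cfg
            )
            res_ga = _residuals_deg(preds_ga, test_gt)
        replicates.append(
            ReplicateResult(
                bias_deg=float(res_gt.mean()),
                rmse_deg=float(np.sqrt(np.mean(res_gt**2))),
                residuals_gt_deg=res_gt,
                residuals_noisy_deg=res_noisy,
                residuals_ga_deg=res_ga,
            )
        )
        logger.info(
            "replicate %d/%d: bias %.3f deg, rmse %.2f deg",
            k + 1,
            m_replicates,
            replicates[-1].bias_deg,
            replicates[-1].rmse_deg,
        )
    agg = aggregate_bias([r.bias_deg for r in replicates])
    run = EvaluationRun(
        n_train=n_train,
        replicates=replicates,
        aggregate_bias_deg=agg,
        armse_deg=armse([r.residuals_gt_deg for r in replicates]),
        armse_noisy_deg=armse([r.residuals_noisy_deg for r in replicates]),
        aggregate_bias_ga_deg=(
            aggregate_bias([float(np.mean(r.residuals_ga_deg)) for r in replicates])
            if group_average_k
            else None
        ),
        armse_ga_deg=(
            armse([r.residuals_ga_deg for r in replicates]) if group_average_k else None
        ),
    )
    return run


def learning_curve(
    n_grid: list[int],
    m_replicates: int,
    seed: int,
    noise_sd_deg: float = 20.0,
    fit_floor_deg: float = 0.0,
    **experiment_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Bias and ARMSE versus training-set size, with a power-law fit.

    Trains ``m_replicates`` networks per grid point on independent datasets
    (cross-validation-like), evaluating each cell against both ground truth
    and the noisy labels.  A failed training cell is recorded as invalid and
    the run continues.  ``log(ARMSE - floor)`` is fitted against ``log N`` by
    least squares; the smallest-N point is excluded when its replicate spread
    exceeds its mean (unstable head of the curve).
    """
    if sorted(n_grid) != list(n_grid):
        raise ValueError("n_grid must be ascending")
    root = np.random.SeedSequence(seed)
    rows = []
    for n, cell_seed in zip(n_grid, root.spawn(len(n_grid))):
        try:
            run = run_bias_experiment(
                n, m_replicates, int(cell_seed.generate_state(1)[0] % 2**31), **experiment_kwargs
            )
            rows.append(
                {
                    "N": n,
                    "M": m_replicates,
                    "bias_deg": run.aggregate_bias_deg,
                    "armse_deg": run.armse_deg,
                    "armse_noisy_deg": run.armse_noisy_deg,
                    "armse_ga_deg": run.armse_ga_deg,
                    "rmse_spread_deg": float(np.std([r.rmse_deg for r in run.replicates])),
                    "valid": True,
                }
            )
        except Exception as exc:  # training failure: mark cell invalid, continue
            logger.warning("learning-curve cell N=%d failed: %s", n, exc)
            rows.append(
                {"N": n, "M": m_replicates, "bias_deg": np.nan, "armse_deg": np.nan,
                 "armse_noisy_deg": np.nan, "armse_ga_deg": np.nan,
                 "rmse_spread_deg": np.nan, "valid": False}
            )
    table = pd.DataFrame(rows)
    fit = fit_power_law(table, floor_deg=fit_floor_deg)
    return table, fit


def fit_power_law(
    table: pd.DataFrame, floor_deg: float = 0.0, n_boot: int = 200, seed: int = 0
) -> dict:
    """Least-squares exponent of ARMSE(N) ~ N**gamma above a floor.

    Returns the exponent with a bootstrap confidence interval (the exponent
    is reported, not asserted: it depends on architecture and scale).
    """
    valid = table[table["valid"]].copy()
    if len(valid) >= 3:
        head = valid.iloc[0]
        if head["rmse_spread_deg"] > head["armse_deg"]:
            valid = valid.iloc[1:]
    x = np.log(valid["N"].to_numpy(float))
    y = np.log(np.maximum(valid["armse_deg"].to_numpy(float) - floor_deg, 1e-6))
    if x.size < 2:
        return {"exponent": np.nan, "ci_low": np.nan, "ci_high": np.nan}
    slope = np.polyfit(x, y, 1)[0]
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        if np.unique(x[idx]).size < 2:
            continue
        boots.append(np.polyfit(x[idx], y[idx], 1)[0])
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return {"exponent": float(slope), "ci_low": float(lo), "ci_high": float(hi)}


def make_reference_labels(
    predict_angles,
    frame_stacks: list[np.ndarray],
    rate_hz: float = 30.0,
    filter_order: int = 1,
    cutoff_hz: float = 2.0,
    window: int = 52,
    samples_per_trajectory: int = 1,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Reference labels theta_r from per-frame predictions.

    For each trajectory's imagelet stream: predict frame by frame, lift to a
    continuous signal, low-pass (zero-phase Butterworth, the same filter the
    measurement pipeline uses) and subsample a few independent instants.
    Trajectories shorter than the filter window are excluded (logged).
    Returns ``(t_selected, theta_r)`` per retained trajectory.
    """
    from .dynamics import unwrap_p1

    rng = np.random.default_rng(rng)
    out = []
    for frames in frame_stacks:
        if frames.shape[0] <= window:
            logger.info("make_reference_labels: trajectory of %d frames excluded "
                        "(shorter than filter window %d)", frames.shape[0], window)
            continue
        preds = predict_angles(frames)
        t = np.arange(frames.shape[0]) / rate_hz
        sig = OrientationSignal(t, unwrap_p1(preds), rate_hz)
        smooth = lowpass(sig, order=filter_order, cutoff_hz=cutoff_hz, window=window)
        idx = np.sort(rng.choice(t.size, size=min(samples_per_trajectory, t.size), replace=False))
        out.append((t[idx], smooth.theta[idx]))
    return out
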