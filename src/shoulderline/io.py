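"""Interchange formats: 16-bit PNG imagelet datasets, CSV trajectories and
signals, and single-file estimator checkpoints.

Conventions: angles are serialized in degrees (columns ``*_deg``), time in
seconds, positions in metres, depth in millimetres (PNG value = depth in mm;
smaller = closer to the sensor = higher above the floor).  Every artifact
carries the producing configuration hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .dynamics import OrientationSignal, Trajectory
from .synthgen import Imagelet, SyntheticSample

__all__ = [
    "config_hash",
    "write_imagelet_dataset",
    "read_imagelet_dataset",
    "write_trajectories",
    "read_trajectories",
    "write_signal",
    "read_signal",
    "save_checkpoint",
    "load_checkpoint",
]


def config_hash(obj) -> str:
    """Short deterministic hash of a configuration object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_imagelet_dataset(directory, samples: list[SyntheticSample], config=None) -> Path:
    """Write samples as 16-bit grayscale PNGs plus a manifest.csv.

    Depth is quantized to 1 mm integers, so the round trip is lossless for
    integral depths and within 0.5 mm otherwise.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config) if config is not None else ""
    rows = []
    for i, s in enumerate(samples):
        name = f"imagelet_{i:06d}.png"
        arr = np.clip(np.round(s.imagelet.pixels), 0, 65535).astype(np.uint16)
        Image.fromarray(arr).save(directory / name)
        rows.append(
            {
                "id": i,
                "file": name,
                "theta_gt_deg": np.rad2deg(s.theta_gt),
                "theta_label_deg": np.rad2deg(s.theta_label),
                "noise_sd_deg": s.noise_sd_deg,
                "background_mm": s.imagelet.background_depth_mm,
                "pixel_pitch_m": s.imagelet.pixel_pitch_m,
                "config_hash": chash,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return directory


def read_imagelet_dataset(directory) -> list[SyntheticSample]:
    """Read a PNG + manifest dataset back; bit-exact for 1 mm-quantized depth.

    Missing files referenced by the manifest are a hard error naming the ids;
    non-16-bit PNGs are rejected.
    """
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    missing = [
        int(r.id) for r in manifest.itertuples() if not (directory / r.file).exists()
    ]
    if missing:
        raise FileNotFoundError(f"manifest references missing imagelets: ids {missing}")
    samples = []
    for r in manifest.itertuples():
        img = Image.open(directory / r.file)
        if img.mode not in ("I;16", "I"):
            raise ValueError(
                f"imagelet id {int(r.id)}: expected 16-bit grayscale PNG, got mode {img.mode!r}"
            )
        px = np.asarray(img, dtype=np.float32)
        samples.append(
            SyntheticSample(
                Imagelet(px, float(r.background_mm), float(r.pixel_pitch_m)),
                float(np.deg2rad(r.theta_gt_deg)),
                float(np.deg2rad(r.theta_label_deg)),
                float(r.noise_sd_deg),
            )
        )
    return samples


def write_trajectories(path, trajectories: list[Trajectory]) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame(
            {"id": traj.pedestrian_id, "t_s": traj.t, "x_m": traj.x, "y_m": traj.y}
        )
        for traj in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_trajectories(path, expected_rate_hz: float = 30.0) -> list[Trajectory]:
    """Read a CSV of (id, t_s, x_m, y_m) rows into per-pedestrian trajectories.

    Rows are grouped by id and sorted by time; non-monotone time within an id
    is an error.  A sampling rate deviating from the expected one by more
    than 1% is flagged with a warning (pass-through, no resampling).
    """
    import warnings

    df = pd.read_csv(path)
    required = {"id", "t_s", "x_m", "y_m"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    out = []
    for pid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("t_s")
        t = grp["t_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"trajectory {pid!r}: non-monotone time")
        traj = Trajectory(str(pid), t, grp["x_m"].to_numpy(float), grp["y_m"].to_numpy(float))
        if t.size >= 2 and abs(traj.rate_hz - expected_rate_hz) > 0.01 * expected_rate_hz:
            warnings.warn(
                f"trajectory {pid!r}: sampling rate {traj.rate_hz:.2f} Hz deviates from "
                f"the expected {expected_rate_hz} Hz; passed through unresampled"
            )
        out.append(traj)
    return out


def write_signal(path, sig: OrientationSignal) -> Path:
    path = Path(path)
    pd.DataFrame({"t_s": sig.t, "theta_deg": np.rad2deg(sig.theta)}).to_csv(path, index=False)
    return path


def read_signal(path) -> OrientationSignal:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(float)
    rate = 1.0 / float(np.mean(np.diff(t))) if t.size >= 2 else np.nan
    return OrientationSignal(t, np.deg2rad(df["theta_deg"].to_numpy(float)), rate)


def save_checkpoint(path, est) -> Path:
    """Single-file estimator checkpoint: weights + JSON config + metadata."""
    path = Path(path)
    payload = {f"param_{i}": p for i, p in enumerate(est.net.params)}
    meta = {
        "net_config": dataclasses.asdict(est.net_config),
        "train_config": dataclasses.asdict(est.train_config),
        "loss_history": est.loss_history,
        "background_mm": est.background_mm,
        "contrast_mm": est.contrast_mm,
        "metadata": est.metadata,
        "config_hash": config_hash(est.net_config),
    }
    np.savez_compressed(path, meta=json.dumps(meta), **payload)
    return path


def load_checkpoint(path):
    from . import nn
    from .estimator import NetworkConfig, TrainedEstimator, TrainingConfig

    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        params = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
    ncfg = meta["net_config"]
    ncfg["conv_blocks"] = tuple(tuple(b) for b in ncfg["conv_blocks"])
    ncfg["dense_widths"] = tuple(ncfg["dense_widths"])
    net_config = NetworkConfig(**ncfg)
    net = nn.SmallCNN(
        net_config.imagelet_size,
        list(net_config.conv_blocks),
        list(net_config.dense_widths),
        net_config.bin_count,
        np.random.default_rng(0),
        pool=net_config.pool,
    )
    if len(net.params) != len(params):
        raise ValueError("checkpoint does not match the recorded architecture")
    net.params = [p.copy() for p in params]
    return TrainedEstimator(
        net,
        net_config,
        TrainingConfig(**meta["train_config"]),
        list(meta["loss_history"]),
        meta["background_mm"],
        meta["contrast_mm"],
        meta["metadata"],
    )
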