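import numpy as np
import pytest

from shoulderline import synthgen as sg


@pytest.fixture(scope="session")
def clean_sample():
    """One noise-free, head-centered synthetic imagelet at theta = 20 deg."""
    return sg.generate_imagelet(
        np.deg2rad(20.0), rng=3, ranges=sg.EllipsePairRanges().noiseless()
    )


@pytest.fixture(scope="session")
def small_trained_estimator():
    """A quickly trained estimator on a small synthetic set (shared across
    tests that need a real network but not a high-accuracy one)."""
    from shoulderline import estimator as est_mod

    px, gt, lab = sg.generate_imagelet_batch(
        3000, rng=11, size=32, pixel_pitch_m=0.04, noise_sd_deg=20.0
    )
    tset = est_mod.build_training_set(px, lab)
    net_cfg = est_mod.NetworkConfig(
        imagelet_size=32, conv_blocks=((8, 3, 2), (16, 3, 2), (32, 3, 2)), dense_widths=(64,)
    )
    cfg = est_mod.TrainingConfig(epochs=6, rng_seed=5)
    return est_mod.train(tset, net_cfg, cfg)
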