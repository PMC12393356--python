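"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from burstkin.core import SimulationConfig, WalkerSpec
from burstkin.segmentation import SegmentationParams
from burstkin.synthetic import EllipseNucleus, render_movie, simulate_tracks


@pytest.fixture(scope="session")
def seg_params():
    """Segmentation parameters scaled to the small synthetic test frames."""
    return SegmentationParams(
        nucleus_blur_sigma=3,
        nucleus_rolling_radius=60,
        nucleus_size_range=(200, 4000),
        dog_radius_small=1.2,
        dog_radius_big=2.5,
        fish_rolling_radius=60,
        fish_blur_sigma=2,
        spot_dog_small=0.8,
        spot_dog_big=2.5,
        pixel_size_um=0.1,
    )


@pytest.fixture(scope="session")
def locus_movie():
    """One eccentric nucleus with a stationary locus: drift-test fixture."""
    cfg = SimulationConfig(
        n_frames=10, image_shape=(128, 128), frame_interval_s=15.0,
        rng_seed=37, localization_noise_um=0.0, snr=15, background_level=100.0,
    )
    nucleus = EllipseNucleus((64, 64), (50, 28), angle_deg=20, label=1)
    tracks = simulate_tracks(
        [WalkerSpec(model="brownian", D_um2_s=0.0, start_xy_um=(8.5, 5.0),
                    lifetime_frames=cfg.n_frames)],
        cfg,
    )
    movie, gt = render_movie(tracks, [], [nucleus], None, cfg)
    return cfg, movie, gt
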