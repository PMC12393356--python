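"""Segmentation: threshold rules, per-nucleus burst statistic, distance maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstkin.core import SimulationConfig, WalkerSpec
from burstkin.segmentation import (
    SegmentationParams,
    auto_threshold,
    build_organelle_distance_maps,
    burst_threshold,
    call_bursts_in_nucleus,
    segment_nuclei_burst_movie,
    segment_nuclei_fish,
    segment_organelles,
    segment_spots_dog,
    smt_nuclear_qc,
    suppress_extranuclear,
    threshold_huang,
)
from burstkin.synthetic import EllipseNucleus, render_movie, simulate_tracks


def three_ellipse_frame(rng):
    rr, cc = np.mgrid[0:192, 0:192]
    masks = [
        ((rr - 48) / 20) ** 2 + ((cc - 48) / 16) ** 2 <= 1,
        ((rr - 48) / 15) ** 2 + ((cc - 140) / 20) ** 2 <= 1,
        ((rr - 140) / 18) ** 2 + ((cc - 96) / 18) ** 2 <= 1,
    ]
    img = np.full((192, 192), 20.0)
    for m in masks:
        img[m] = 100.0
    return img + rng.normal(0, 3, img.shape), masks


class TestThresholds:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    def test_burst_threshold_formula_exact(self, median):
        assert burst_threshold(median) == 5.0 + 0.55 * median

    def test_mean_threshold_is_pixel_mean(self):
        img = np.arange(100, dtype=float).reshape(10, 10)
        assert auto_threshold(img, "mean") == img.mean()

    def test_huang_separates_bimodal_image(self):
        rng = np.random.default_rng(0)
        labels = np.concatenate([np.zeros(5000, bool), np.ones(2000, bool)])
        img = np.where(labels, rng.normal(100, 5, 7000), rng.normal(20, 2, 7000))
        thr = threshold_huang(img.reshape(70, 100))
        assert thr < img[labels].min()
        assert ((img > thr) != labels).mean() < 1e-3

    @pytest.mark.parametrize("method", ["mean", "huang", "default"])
    def test_constant_image_has_no_threshold(self, method):
        with pytest.raises(ValueError):
            auto_threshold(np.zeros((8, 8)), method)


class TestNucleusSegmentation:
    def test_three_ellipses_found_with_high_coverage(self, seg_params):
        img, masks = three_ellipse_frame(np.random.default_rng(1))
        nm = segment_nuclei_burst_movie(img, seg_params)
        assert len(nm.labels) == 3
        for true_mask in masks:
            label = np.bincount(nm.label_image[true_mask]).argmax()
            assert label > 0
            coverage = (nm.label_image[true_mask] == label).mean()
            assert coverage >= 0.90

    def test_undersized_object_filtered(self, seg_params):
        from dataclasses import replace

        rng = np.random.default_rng(2)
        img = np.full((96, 96), 20.0)
        rr, cc = np.mgrid[0:96, 0:96]
        img[(rr - 48) ** 2 + (cc - 48) ** 2 <= 36] = 120.0
        noisy = img + rng.normal(0, 2, img.shape)
        # in range with the default bounds, below a raised minimum
        assert segment_nuclei_burst_movie(noisy, seg_params).labels == [1]
        strict = replace(seg_params, nucleus_size_range=(600, 4000))
        assert segment_nuclei_burst_movie(noisy, strict).labels == []

    def test_constant_frame_rejected(self, seg_params):
        with pytest.raises(ValueError):
            segment_nuclei_burst_movie(np.zeros((64, 64)), seg_params)

    def test_label_medians_from_source_channel(self, seg_params):
        img, masks = three_ellipse_frame(np.random.default_rng(3))
        nm = segment_nuclei_burst_movie(img, seg_params)
        for lab in nm.labels:
            assert nm.median_intensity[lab] == pytest.approx(100.0, abs=5)


class TestSuppression:
    def _mask(self, seg_params):
        img, _ = three_ellipse_frame(np.random.default_rng(4))
        return img, segment_nuclei_burst_movie(img, seg_params)

    def test_outside_set_to_90pct_of_median(self, seg_params):
        img, nm = self._mask(seg_params)
        lab = nm.labels[0]
        out = suppress_extranuclear(img, nm, lab)
        outside = nm.label_image != lab
        assert np.allclose(out[outside], 0.9 * nm.median_intensity[lab])

    def test_inside_untouched_and_idempotent(self, seg_params):
        img, nm = self._mask(seg_params)
        lab = nm.labels[1]
        once = suppress_extranuclear(img, nm, lab)
        inside = nm.label_image == lab
        assert np.array_equal(once[inside], img[inside])
        twice = suppress_extranuclear(once, nm, lab)
        assert np.array_equal(once, twice)

    def test_unknown_label_rejected(self, seg_params):
        img, nm = self._mask(seg_params)
        with pytest.raises(KeyError):
            suppress_extranuclear(img, nm, 99)


class TestBurstCalls:
    def test_flat_frame_yields_no_spots(self, seg_params):
        spots = call_bursts_in_nucleus(np.full((64, 64), 50.0), 50.0, seg_params)
        assert spots == []

    def test_rendered_burst_found_within_one_pixel(self, seg_params):
        cfg = SimulationConfig(n_frames=2, image_shape=(96, 96),
                               frame_interval_s=120.0, rng_seed=5, snr=10,
                               background_level=30.0,
                               localization_noise_um=0.0)
        nucleus = EllipseNucleus((48, 48), (34, 30), label=1)
        rr, cc = np.mgrid[0:96, 0:96]
        img = np.where(nucleus.mask((96, 96)), 30.0, 27.0)
        # bright focus at a known position, 3x the single-spot SNR reference
        amp = 3 * cfg.snr * cfg.noise_sigma
        img = img + amp * np.exp(-((rr - 40) ** 2 + (cc - 60) ** 2) / (2 * 1.2**2))
        img = np.random.default_rng(5).poisson(img).astype(float)
        spots = call_bursts_in_nucleus(img, 30.0, seg_params, nucleus_label=1)
        assert len(spots) == 1
        assert abs(spots[0].x_um - 6.0) <= 0.1
        assert abs(spots[0].y_um - 4.0) <= 0.1
        assert spots[0].dog_value > burst_threshold(30.0)


class TestFishSegmentation:
    def test_touching_nuclei_split_by_watershed(self, seg_params):
        rng = np.random.default_rng(6)
        rr, cc = np.mgrid[0:128, 0:128]
        m1 = ((rr - 64) / 20) ** 2 + ((cc - 45) / 16) ** 2 <= 1
        m2 = ((rr - 64) / 20) ** 2 + ((cc - 80) / 16) ** 2 <= 1
        img = np.where(m1 | m2, 200.0, 20.0)
        img[60:64, 40:44] = 20.0  # a hole inside nucleus 1
        stack = np.stack([img * 0.8, img, img * 0.9])
        stack = stack + rng.normal(0, 3, stack.shape)
        nm = segment_nuclei_fish(stack, seg_params)
        assert len(nm.labels) == 2
        assert nm.label_image[62, 42] != 0  # hole filled

    def test_small_particles_removed(self, seg_params):
        from dataclasses import replace

        rng = np.random.default_rng(7)
        rr, cc = np.mgrid[0:128, 0:128]
        img = np.full((128, 128), 20.0)
        img[((rr - 50) / 18) ** 2 + ((cc - 50) / 18) ** 2 <= 1] = 200.0
        img[100:103, 100:103] = 200.0  # tiny debris particle
        params = replace(seg_params, fish_min_size=40)
        nm = segment_nuclei_fish((img + rng.normal(0, 2, img.shape))[None],
                                 params)
        assert len(nm.labels) == 1
        assert nm.label_image[101, 101] == 0


class TestSpotDoG:
    def test_dna_threshold_is_k_times_sd(self, seg_params):
        rng = np.random.default_rng(8)
        img = rng.normal(50, 10, (64, 64))
        # no DoG value can reach 3*SD(channel)=~30 on pure noise
        assert segment_spots_dog(img, "dna_track", seg_params) == []

    def test_unknown_mode_rejected(self, seg_params):
        with pytest.raises(ValueError):
            segment_spots_dog(np.zeros((8, 8)), "nope", seg_params)

    def test_rendered_locus_detected_reliably(self, seg_params):
        cfg = SimulationConfig(n_frames=60, image_shape=(96, 96),
                               frame_interval_s=15.0, rng_seed=9,
                               localization_noise_um=0.0, snr=8,
                               background_level=30.0)
        nucleus = EllipseNucleus((48, 48), (34, 30), label=1)
        tracks = simulate_tracks(
            [WalkerSpec(model="confined", D_um2_s=0.005, Rc_um=0.8,
                        start_xy_um=(4.8, 4.8), lifetime_frames=60)], cfg)
        movie, gt = render_movie(tracks, [], [nucleus], None, cfg)
        inside = gt.nuclei_mask == 1
        hits = 0
        for f in range(60):
            frame = movie.channel("dna")[f].copy()
            frame[~inside] = 27.0
            spots = segment_spots_dog(frame, "dna_track", seg_params, frame=f)
            true = tracks[0].xy_um[f]
            if any(np.hypot(s.x_um - true[0], s.y_um - true[1]) <= 0.1
                   for s in spots):
                hits += 1
        assert hits / 60 >= 0.99

    def test_organelle_mode_masks_blobs(self, seg_params):
        rng = np.random.default_rng(10)
        rr, cc = np.mgrid[0:96, 0:96]
        img = np.full((96, 96), 30.0)
        img[(rr - 30) ** 2 + (cc - 30) ** 2 <= 16] = 120.0
        img[(rr - 70) ** 2 + (cc - 60) ** 2 <= 16] = 120.0
        mask = segment_organelles(img + rng.normal(0, 2, img.shape), seg_params)
        assert mask[30, 30] and mask[70, 60]
        assert not mask[10, 80]


class TestDistanceMaps:
    def test_single_pixel_organelle_distances(self):
        mask = np.zeros((16, 16), bool)
        mask[5, 5] = True
        om = build_organelle_distance_maps(mask, 0.1)
        assert om.external_dist[5, 8] == pytest.approx(0.3)
        assert om.external_dist[5, 6] == pytest.approx(0.1)  # boundary adjacent
        assert om.internal_dist[5, 5] == pytest.approx(0.1)

    def test_internal_external_disjoint_on_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            mask = rng.random((32, 32)) < 0.3
            if mask.all() or not mask.any():
                continue
            om = build_organelle_distance_maps(mask, 0.1)
            assert np.all(om.internal_dist * om.external_dist == 0)
            assert np.all((om.internal_dist > 0) == mask)
            assert np.all((om.external_dist > 0) == ~mask)

    @pytest.mark.parametrize("mask", [np.ones((8, 8), bool), np.zeros((8, 8), bool)])
    def test_degenerate_masks_rejected(self, mask):
        with pytest.raises(ValueError):
            build_organelle_distance_maps(mask, 0.1)


class TestSmtQC:
    def test_uniform_disc_means(self):
        rr, cc = np.mgrid[0:96, 0:96]
        disc = (rr - 48) ** 2 + (cc - 48) ** 2 <= 900
        red = np.where(disc, 10.0, 0.0)
        blue = np.where(disc, 4.0, 0.0)
        area, mean_red, mean_blue = smt_nuclear_qc(red, blue)
        assert mean_red == pytest.approx(10.0)
        assert mean_blue == pytest.approx(4.0)
        assert area == pytest.approx(disc.sum(), rel=0.10)

    def test_constant_red_channel_rejected(self):
        with pytest.raises(ValueError):
            smt_nuclear_qc(np.zeros((32, 32)), np.zeros((32, 32)))

    def test_synthetic_nucleus_area_within_10pct(self, locus_movie):
        _, movie, gt = locus_movie
        red = movie.channel("dna")[0]
        blue = movie.channel("nuclear")[0]
        area, _, _ = smt_nuclear_qc(red, blue)
        truth = (gt.nuclei_mask > 0).sum()
        assert area == pytest.approx(truth, rel=0.10)
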