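"""Vessel amount, skeleton decomposition, zone-B geometry, and SNR profiles."""

import math

import numpy as np
import pytest
from scipy import ndimage

from fundus_eval.preprocessing import FundusImage
from fundus_eval.synthetic import SynthConfig, generate_fundus
from fundus_eval.vessel_metrics import (
    DiscGeometry,
    MetricConfig,
    VesselSample,
    compute_image_metrics,
    count_vessel_pixels,
    point_snr,
    ridge_segment,
    sample_points,
    skeletonize_mask,
    zone_b_mask,
)

from conftest import MASTER_SEED


class TestCountVesselPixels:
    def test_empty_mask(self):
        assert count_vessel_pixels(np.zeros((5, 5), bool)) == 0

    def test_hand_countable(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 1:4] = 1
        assert count_vessel_pixels(mask) == 3

    def test_255_convention(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0, 0] = 255
        assert count_vessel_pixels(mask) == 1

    def test_non_binary_rejected(self):
        bad = np.zeros((4, 4), dtype=np.uint8)
        bad[1, 1] = 7
        with pytest.raises(ValueError):
            count_vessel_pixels(bad)

    def test_matches_generator_truth(self, small_image_truth):
        _, gt = small_image_truth
        assert count_vessel_pixels(gt.vessel_mask) == gt.vessel_pixel_count


class TestSkeletonizeMask:
    def test_straight_bar_single_midline_segment(self):
        mask = np.zeros((20, 40), bool)
        mask[8:11, 5:35]
        mask[8:11, 5:35] = True
        skel, segs = skeletonize_mask(mask)
        assert len(segs) == 1
        path = segs[0].path
        assert np.all(np.abs(path[:, 0] - 9) <= 1)  # on/next to the midline
        assert path[:, 1].min() >= 5 and path[:, 1].max() <= 34

    def test_y_mask_three_segments(self):
        mask = np.zeros((60, 60), bool)
        for i in range(25):
            mask[30, 5 + i] = True
        for i in range(20):
            mask[30 - i, 30 + i] = True
            mask[30 + i, 30 + i] = True
        mask = ndimage.binary_dilation(mask, iterations=1)
        _, segs = skeletonize_mask(mask)
        assert len(segs) == 3

    def test_empty_mask_empty_skeleton(self):
        skel, segs = skeletonize_mask(np.zeros((10, 10), bool))
        assert not skel.any() and segs == []

    def test_unbranched_tree_segment_count(self):
        """A single unbranched vessel yields one segment give or take spurs."""
        cfg = SynthConfig(image_size=256, seed=4, n_root_vessels=1,
                          branch_probability=0.0, tortuosity=0.02)
        _, gt = generate_fundus(cfg)
        assert len(gt.centerlines) == 1
        _, segs = skeletonize_mask(gt.vessel_mask)
        long_segs = [s for s in segs if len(s.path) >= 5]
        assert 1 <= len(segs) <= 3 and len(long_segs) == 1

    def test_paths_ordered_unit_steps(self, small_image_truth):
        _, gt = small_image_truth
        _, segs = skeletonize_mask(gt.vessel_mask)
        for seg in segs[:50]:
            steps = np.abs(np.diff(seg.path, axis=0)).max(axis=1)
            assert (steps == 1).all()


class TestZoneBMask:
    @pytest.mark.parametrize("D", [50, 100, 150])
    def test_area_matches_annulus(self, D):
        disc = DiscGeometry((511.5, 511.5), float(D))
        zb = zone_b_mask(disc, (1024, 1024))
        analytic = 5 * math.pi * D * D
        assert zb.sum() == pytest.approx(analytic, rel=0.01)

    def test_radial_inequality_boundary(self):
        disc = DiscGeometry((512.0, 512.0), 100.0)
        zb = zone_b_mask(disc, (1024, 1024))
        assert not zb[512, 512 + 199]   # 1.99 D
        assert zb[512, 512 + 200]       # 2.00 D exactly
        assert zb[512, 512 + 300]       # 3.00 D exactly
        assert not zb[512, 512 + 301]

    def test_radial_inequality_exact_everywhere(self):
        disc = DiscGeometry((60.0, 70.0), 21.0)
        zb = zone_b_mask(disc, (256, 256))
        rr, cc = np.nonzero(zb)
        dist = np.hypot(rr - 60.0, cc - 70.0)
        assert (dist >= 2 * 21.0).all() and (dist <= 3 * 21.0).all()

    def test_clipped_annulus_smaller_than_analytic(self):
        disc = DiscGeometry((127.5, 127.5), 60.0)
        zb = zone_b_mask(disc, (256, 256))
        assert 0 < zb.sum() < 0.99 * 5 * math.pi * 60**2


def _straight_setup(angle_deg=0.0, length=180, width=5):
    """A straight tube through a 220^2 frame at the given orientation."""
    size = 260
    mask = np.zeros((size, size), bool)
    c0 = np.array([size / 2, size / 2])
    t = np.array([math.sin(math.radians(angle_deg)),
                  math.cos(math.radians(angle_deg))])
    for s in np.linspace(-length / 2, length / 2, 2 * length):
        p = c0 + s * t
        rr, cc = np.mgrid[-3:4, -3:4]
        keep = rr**2 + cc**2 <= (width / 2) ** 2
        r = (np.round(p[0]) + rr[keep]).astype(int)
        c = (np.round(p[1]) + cc[keep]).astype(int)
        mask[r, c] = True
    return mask


class TestSamplePoints:
    def test_even_spacing_on_straight_run(self):
        mask = np.zeros((40, 200), bool)
        mask[18:23, 10:190] = True
        _, segs = skeletonize_mask(mask)
        zone = np.zeros_like(mask)
        zone[:, 40:141] = True  # a 100-px in-zone window
        pts = sample_points(segs, zone, mask, n_per_segment=5)
        cols = sorted(p.position[1] for p in pts)
        assert np.allclose(cols, [50, 70, 90, 110, 130], atol=1.0)

    def test_horizontal_tangent_axis_aligned(self):
        mask = np.zeros((40, 200), bool)
        mask[18:23, 10:190] = True
        _, segs = skeletonize_mask(mask)
        zone = np.ones_like(mask)
        pts = sample_points(segs, zone, mask)
        for p in pts:
            assert abs(abs(p.tangent[1]) - 1.0) < 1e-6
            assert abs(abs(p.normal[0]) - 1.0) < 1e-6
            assert abs(float(p.tangent @ p.normal)) < 1e-9

    @pytest.mark.parametrize("angle", [0, 23, 45, 67, 90, 113, 135, 158])
    def test_tangent_accuracy_eight_orientations(self, angle):
        mask = _straight_setup(angle_deg=angle)
        _, segs = skeletonize_mask(mask)
        zone = np.ones_like(mask)
        pts = sample_points(segs, zone, mask)
        truth = np.array([math.sin(math.radians(angle)),
                          math.cos(math.radians(angle))])
        assert pts
        for p in pts:
            err = math.degrees(math.acos(min(1.0, abs(float(p.tangent @ truth)))))
            assert err < 5.0

    def test_short_runs_skipped(self):
        mask = np.zeros((40, 200), bool)
        mask[18:23, 10:190] = True
        _, segs = skeletonize_mask(mask)
        zone = np.zeros_like(mask)
        zone[:, 95:100] = True  # 5-px window < min_length
        assert sample_points(segs, zone, mask, min_length=10.0) == []

    def test_positions_on_skeleton_inside_zone(self):
        """Containment over a batch of random trees."""
        for seed in range(10):
            img, gt = generate_fundus(SynthConfig(image_size=256, seed=700 + seed))
            skel, segs = skeletonize_mask(gt.vessel_mask)
            zb = zone_b_mask(gt.disc, gt.vessel_mask.shape)
            for p in sample_points(segs, zb, gt.vessel_mask):
                r, c = np.round(p.position).astype(int)
                assert zb[r, c]
                # subpixel position lies between ordered skeleton pixels
                assert skel[max(0, r - 1):r + 2, max(0, c - 1):c + 2].any()

    def test_half_width_matches_tube(self):
        mask = _straight_setup(angle_deg=30, width=6)
        _, segs = skeletonize_mask(mask)
        pts = sample_points(segs, np.ones_like(mask), mask)
        hw = np.median([p.half_width for p in pts])
        assert hw == pytest.approx(3.0, abs=0.8)


def _flat_image(shape, level=0.5):
    return FundusImage(np.full(shape, level))


class TestPointSNR:
    def _sample(self, pos, normal=(1.0, 0.0), hw=2.5):
        normal = np.asarray(normal, float)
        tangent = np.array([-normal[1], normal[0]])
        return VesselSample(position=np.asarray(pos, float), tangent=tangent,
                            normal=normal, half_width=hw, segment_id=0)

    def test_constant_image_degenerate_noise(self):
        mask = np.zeros((64, 64), bool)
        mask[30:33, :] = True
        rec, why = point_snr(_flat_image((64, 64)), self._sample((31.0, 32.0)),
                             mask)
        assert rec is None and why == "degenerate_noise"

    def test_out_of_frame_band_dropped(self):
        mask = np.zeros((64, 64), bool)
        mask[2:5, :] = True
        rec, why = point_snr(_flat_image((64, 64)), self._sample((3.0, 32.0)),
                             mask)
        assert rec is None and why == "out_of_frame"

    def test_band_hitting_other_vessel_dropped(self):
        px = np.full((64, 64), 0.6)
        rng = np.random.default_rng(0)
        px += rng.normal(0, 0.05, px.shape)
        mask = np.zeros((64, 64), bool)
        mask[30:33, :] = True
        mask[36, :] = True  # neighbouring vessel inside the band
        rec, why = point_snr(FundusImage(np.clip(px, 0, 1)),
                             self._sample((31.0, 32.0), hw=1.5), mask)
        assert rec is None and why == "band_hits_vessel"

    def test_snr_identity_and_analytic_value(self):
        """Noiseless background with a known checker pattern: snr==signal/noise."""
        rng = np.random.default_rng(MASTER_SEED)
        px = np.clip(0.6 + rng.normal(0, 0.05, (64, 64)), 0, 1)
        mask = np.zeros((64, 64), bool)
        mask[30:33, :] = True
        px[mask] = 0.5
        rec, why = point_snr(FundusImage(px), self._sample((31.0, 32.0), hw=1.0),
                             mask)
        assert rec is not None
        assert rec.snr == rec.signal / rec.noise
        assert rec.signal == pytest.approx(0.5, abs=1e-9)

    def test_single_point_snr_near_analytic(self):
        """Typical per-point SNR error stays within the 25% finite-sample band."""
        cfg = SynthConfig(image_size=384, seed=MASTER_SEED, background_level=0.8,
                          vessel_contrast=0.3, noise_sigma=0.05)
        img, gt = generate_fundus(cfg)
        m, recs = compute_image_metrics(img, gt.vessel_mask, gt.disc)
        assert len(recs) >= 10
        errors = np.array([abs(r.snr - 10.0) / 10.0 for r in recs])
        assert np.median(errors) < 0.25
        assert abs(np.mean([r.snr for r in recs]) - 10.0) / 10.0 < 0.10

    def test_higher_contrast_lowers_snr(self):
        """Doubling the intensity drop c at fixed b, sigma lowers signal/noise."""
        means = []
        for c in (0.15, 0.30):
            snrs = []
            for seed in range(4):
                cfg = SynthConfig(image_size=256, seed=800 + seed,
                                  vessel_contrast=c, noise_sigma=0.1)
                img, gt = generate_fundus(cfg)
                m, _ = compute_image_metrics(img, gt.vessel_mask, gt.disc)
                snrs.append(m.mean_snr)
            means.append(np.nanmean(snrs))
        assert means[1] < means[0]


class TestComputeImageMetrics:
    def test_empty_mask(self, small_image_truth):
        img, _ = small_image_truth
        disc = DiscGeometry((128.0, 180.0), 30.0)
        m, recs = compute_image_metrics(img, np.zeros(img.pixels.shape, bool), disc)
        assert m.vessel_amount == 0 and m.n_points == 0 and recs == []
        assert np.isnan(m.mean_snr)

    def test_deterministic(self, small_image_truth):
        img, gt = small_image_truth
        m1, _ = compute_image_metrics(img, gt.vessel_mask, gt.disc)
        m2, _ = compute_image_metrics(img, gt.vessel_mask, gt.disc)
        assert m1 == m2

    def test_mean_snr_tracks_ground_truth(self):
        """Average over a batch of default images recovers (b-c)/sigma."""
        snrs, expected = [], None
        for seed in range(12):
            img, gt = generate_fundus(SynthConfig(image_size=320, seed=500 + seed))
            m, _ = compute_image_metrics(img, gt.vessel_mask, gt.disc)
            if np.isfinite(m.mean_snr):
                snrs.append(m.mean_snr)
            expected = gt.expected_snr
        assert len(snrs) >= 10
        assert np.mean(snrs) == pytest.approx(expected, rel=0.10)


class TestRidgeSegment:
    def test_low_noise_dice_overlap(self):
        img, gt = generate_fundus(
            SynthConfig(image_size=512, seed=2, noise_sigma=0.02)
        )
        pred = ridge_segment(img)
        dice = 2 * (pred & gt.vessel_mask).sum() / (pred.sum() + gt.vessel_mask.sum())
        assert dice >= 0.6

    def test_blank_image_empty_mask(self):
        pred = ridge_segment(_flat_image((128, 128), 0.3))
        assert pred.dtype == bool and not pred.any()

    def test_output_strictly_binary(self, small_image_truth):
        img, _ = small_image_truth
        pred = ridge_segment(img)
        assert pred.dtype == bool
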