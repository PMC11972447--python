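"""Tests of the ring-detection pipeline: preprocessing, segmentation, contour
filtering, ellipse fitting and the offset benchmark."""

import numpy as np
import pytest
from skimage import draw, measure

from apc import detect, synthetic
from apc.detect import (
    ANNULUS_PARAMS,
    PHASE_RING_PARAMS,
    ContourStats,
    DetectorParams,
    RingDetectionError,
    detect_offset,
    detect_ring,
    find_ring_contour,
    fit_ellipse,
    preprocess,
    run_benchmark,
    segment_ring,
    to_analysis_scale,
)


def circle_points(center, radius, n=200):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])


class TestPreprocess:
    def test_downscale_dimensions(self):
        img = np.random.default_rng(0).integers(0, 255, (2000, 2400), dtype=np.uint8)
        out = preprocess(img, DetectorParams(downscale=0.2))
        assert out.shape == (400, 480)
        assert out.dtype == np.uint8

    def test_identity_when_disabled(self):
        img = np.random.default_rng(1).integers(0, 255, (64, 64), dtype=np.uint8)
        out = preprocess(img, DetectorParams(downscale=1.0, clahe_clip=0.0))
        assert np.array_equal(out, img)

    def test_constant_image_unchanged_by_clahe(self):
        img = np.full((64, 64), 120, dtype=np.uint8)
        out = preprocess(img, DetectorParams(downscale=1.0))
        assert np.array_equal(out, img)

    def test_too_small_result_rejected(self):
        img = np.zeros((40, 40), dtype=np.uint8)
        with pytest.raises(ValueError):
            preprocess(img, DetectorParams(downscale=0.2))


class TestSegmentRing:
    def test_bright_band_area_matches_analytic(self):
        """Foreground pixel count of a clean bright band matches the analytic
        band area pi*(r_out^2 - r_in^2) within 5%."""
        r_in, r_out = 40.0, 55.0
        img = np.full((200, 200), 50, dtype=np.uint8)
        yy, xx = np.mgrid[0:200, 0:200]
        rho = np.hypot(xx - 99.5, yy - 99.5)
        img[(rho >= r_in) & (rho <= r_out)] = 230
        mask = segment_ring(img, DetectorParams(downscale=1.0, binary_threshold=128))
        analytic = np.pi * (r_out**2 - r_in**2)
        assert np.count_nonzero(mask) == pytest.approx(analytic, rel=0.05)

    def test_all_black_image_rejected(self):
        with pytest.raises(RingDetectionError, match="no segmentation"):
            segment_ring(np.zeros((50, 50), dtype=np.uint8), DetectorParams())

    def test_dark_ring_polarity_segments_phase_ring(self, quiet_model):
        """On a white-screen calibration image the dark phase ring is the
        segmented foreground under dark-ring polarity."""
        truth = synthetic.concentric_truth()
        img, _ = synthetic.generate_bertrand_image(
            truth, quiet_model, seed=1, draw_annulus=False
        )
        pre = preprocess(img, PHASE_RING_PARAMS)
        mask = segment_ring(pre, PHASE_RING_PARAMS)
        contour, stats = find_ring_contour(mask, PHASE_RING_PARAMS)
        fit = fit_ellipse(contour, scale=0.2)
        expect = to_analysis_scale(truth.phase_ring_center[0], 0.2)
        assert fit.center[0] == pytest.approx(expect, abs=1.5)
        assert fit.center[1] == pytest.approx(expect, abs=1.5)


class TestFindRingContour:
    def test_filled_circle_roundness_near_one(self):
        mask = np.zeros((200, 200), bool)
        rr, cc = draw.disk((100, 100), 60)
        mask[rr, cc] = True
        _, stats = find_ring_contour(mask, DetectorParams(min_area=100))
        assert stats.roundness == pytest.approx(1.0, abs=0.05)

    def test_filled_square_rejected_by_roundness(self):
        mask = np.zeros((200, 200), bool)
        mask[50:150, 40:140] = True
        params = DetectorParams(min_area=100, min_roundness=0.85)
        with pytest.raises(RingDetectionError, match="no ring found"):
            find_ring_contour(mask, params)
        # with a permissive bound the same square scores ~pi/4
        _, stats = find_ring_contour(mask, DetectorParams(min_area=100, min_roundness=0.5))
        assert stats.roundness == pytest.approx(np.pi / 4, abs=0.03)

    def test_roundness_equals_eq1_recomputation(self):
        mask = np.zeros((120, 120), bool)
        rr, cc = draw.disk((60, 60), 40)
        mask[rr, cc] = True
        _, stats = find_ring_contour(mask, DetectorParams(min_area=100))
        assert stats.roundness == 4 * np.pi * stats.area / stats.perimeter**2

    def test_small_reflection_discs_ignored(self):
        mask = np.zeros((300, 300), bool)
        rr, cc = draw.disk((150, 150), 70)
        mask[rr, cc] = True
        for c in [(30, 30), (260, 40), (40, 260)]:
            rr, cc = draw.disk(c, 8)
            mask[rr, cc] = True
        contour, stats = find_ring_contour(mask, DetectorParams(min_area=1000))
        assert stats.area == pytest.approx(np.pi * 70**2, rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(RingDetectionError):
            find_ring_contour(np.zeros((50, 50), bool), DetectorParams())


class TestFitEllipse:
    def test_exact_circle(self):
        fit = fit_ellipse(circle_points((100, 80), 40))
        assert fit.center[0] == pytest.approx(100, abs=0.5)
        assert fit.center[1] == pytest.approx(80, abs=0.5)
        assert fit.semi_major == pytest.approx(40, abs=0.5)
        assert fit.semi_minor == pytest.approx(40, abs=0.5)

    def test_exact_axis_aligned_ellipse(self):
        t = np.linspace(0, 2 * np.pi, 300, endpoint=False)
        pts = np.column_stack([60 * np.cos(t), 40 * np.sin(t)])
        fit = fit_ellipse(pts)
        assert fit.center == pytest.approx((0.0, 0.0), abs=0.5)
        assert fit.semi_major == pytest.approx(60, abs=0.5)
        assert fit.semi_minor == pytest.approx(40, abs=0.5)

    def test_matches_independent_least_squares_fit(self):
        """Cross-check against skimage's independent ellipse estimator on
        noisy elliptical data."""
        rng = np.random.default_rng(4)
        t = np.linspace(0, 2 * np.pi, 250, endpoint=False)
        pts = np.column_stack(
            [50 + 45 * np.cos(t), 70 + 30 * np.sin(t)]
        ) + rng.normal(0, 0.3, (250, 2))
        ours = fit_ellipse(pts)
        em = measure.EllipseModel.from_estimate(pts)
        assert em
        assert ours.center[0] == pytest.approx(em.center[0], abs=1.0)
        assert ours.center[1] == pytest.approx(em.center[1], abs=1.0)

    def test_hull_bridges_missing_arc(self):
        """A contour with a bite removed (arc dimmed away) still fits within
        2 px of the full-ellipse center thanks to the convex hull."""
        t = np.linspace(0, 2 * np.pi, 300, endpoint=False)
        keep = (t < 4.0) | (t > 5.2)  # remove ~19% arc
        pts_full = np.column_stack([200 + 80 * np.cos(t), 150 + 55 * np.sin(t)])
        full = fit_ellipse(pts_full)
        bitten = fit_ellipse(pts_full[keep])
        err = np.hypot(
            full.center[0] - bitten.center[0], full.center[1] - bitten.center[1]
        )
        assert err < 2.0

    def test_too_few_points_rejected(self):
        with pytest.raises(RingDetectionError, match="fit failed"):
            fit_ellipse(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(RingDetectionError, match="fit failed"):
            fit_ellipse(pts)

    def test_semi_minor_never_exceeds_semi_major(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
            a, b = rng.uniform(20, 80, 2)
            th = rng.uniform(0, np.pi)
            x = a * np.cos(t) * np.cos(th) - b * np.sin(t) * np.sin(th)
            y = a * np.cos(t) * np.sin(th) + b * np.sin(t) * np.cos(th)
            fit = fit_ellipse(np.column_stack([x, y]))
            assert fit.semi_minor <= fit.semi_major


class TestDetectOffset:
    def test_concentric_offset_near_zero(self, bertrand_concentric):
        img, _ = bertrand_concentric
        off = detect_offset(img)
        assert off.magnitude < 2.0

    def test_known_offset_recovered(self, model):
        """A (30, -12) px analysis-scale offset (150, -60 full-resolution) is
        recovered within 3 px."""
        truth = synthetic.concentric_truth(offset=(150.0, -60.0))
        img, truth = synthetic.generate_bertrand_image(truth, model, seed=7)
        pc = tuple(to_analysis_scale(c, 0.2) for c in truth.phase_ring_center)
        off = detect_offset(img, phase_ring_center=pc)
        assert off.delta_d[0] == pytest.approx(30.0, abs=3.0)
        assert off.delta_d[1] == pytest.approx(-12.0, abs=3.0)

    def test_blank_image_raises(self):
        with pytest.raises(RingDetectionError):
            detect_offset(np.zeros((500, 500), dtype=np.uint8))

    def test_distractor_robustness(self, model):
        """Up to 5 small reflection discs move the offset by < 1 px."""
        truth = synthetic.concentric_truth(offset=(40.0, 20.0))
        pc = tuple(to_analysis_scale(c, 0.2) for c in truth.phase_ring_center)
        img0, _ = synthetic.generate_bertrand_image(truth, model, distractors=0, seed=21)
        img5, _ = synthetic.generate_bertrand_image(truth, model, distractors=5, seed=21)
        d0 = detect_offset(img0, phase_ring_center=pc).delta_d
        d5 = detect_offset(img5, phase_ring_center=pc).delta_d
        assert np.hypot(d0[0] - d5[0], d0[1] - d5[1]) < 1.0

    def test_translation_equivariance(self, model):
        """Shifting the image by an integer vector shifts the detected center
        accordingly (within 1 px at the analysis scale)."""
        truth = synthetic.concentric_truth(offset=(10.0, 4.0))
        img, truth = synthetic.generate_bertrand_image(truth, model, seed=9)
        tx, ty = 40, -25
        shifted = np.roll(np.roll(img, ty, axis=0), tx, axis=1)
        f0 = detect_ring(img, ANNULUS_PARAMS)
        f1 = detect_ring(shifted, ANNULUS_PARAMS)
        assert f1.center[0] - f0.center[0] == pytest.approx(tx * 0.2, abs=1.0)
        assert f1.center[1] - f0.center[1] == pytest.approx(ty * 0.2, abs=1.0)

    def test_scale_bookkeeping(self, model):
        """Analysis-scale detection mapped back to full resolution agrees with
        a full-resolution detection within 1/downscale px."""
        truth = synthetic.concentric_truth(offset=(25.0, -10.0))
        img, truth = synthetic.generate_bertrand_image(truth, model, seed=13)
        fit_small = detect_ring(img, ANNULUS_PARAMS)
        full_params = DetectorParams(
            downscale=1.0, binary_threshold=ANNULUS_PARAMS.binary_threshold,
            min_area=ANNULUS_PARAMS.min_area * 25,
        )
        fit_full = detect_ring(img, full_params)
        cx, cy = fit_small.center_full_resolution
        assert cx == pytest.approx(fit_full.center[0], abs=5.0)
        assert cy == pytest.approx(fit_full.center[1], abs=5.0)


class TestBenchmark:
    def test_small_benchmark_statistics(self):
        res = run_benchmark(n=20, seed=3)
        assert res.n_failed == 0
        assert res.median <= detect.ACCEPTANCE_MARGIN_PX
        assert res.fraction_within_margin == 1.0
        # independent summary oracle over the raw error list
        assert res.median == np.median(res.errors)
        assert res.mean == np.mean(res.errors)
        assert res.std == pytest.approx(np.std(res.errors, ddof=1))

    def test_single_clean_image(self):
        res = run_benchmark(n=1, offset_range=0.0, distractors=0, seed=1, noise_sigma=0.0)
        assert res.errors[0] < 2.0

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            run_benchmark(n=0)
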