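"""Despeckling, star edge detection, ellipse fitting and Kalman tracking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import measure

from aortasweep.phantom import PhantomSpec, render_frame
from aortasweep.segmentation import (
    BModeFrame,
    EllipseFitError,
    SegmentationError,
    TrackLostError,
    BAND_THICKNESS_MM,
    Ellipse,
    SearchBand,
    TrackerState,
    esf_despeckle,
    fit_ellipse,
    gaussian_smooth,
    kalman_step,
    segment_sweep,
    star_edge_candidates,
)


def frame_of(img, spacing=0.35):
    return BModeFrame(np.asarray(img, dtype=float), spacing)


def ring_image(radius=10.0, size=128, spacing=0.35, wall=2.0, attenuation=0.0):
    spec = PhantomSpec(
        base_radius=radius, image_size=size, pixel_spacing=spacing,
        wall_thickness=wall, speckle_sigma=0.0, lateral_attenuation=attenuation,
        tracker_jitter_mm=0.0, tracker_jitter_deg=0.0,
    )
    theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
    contour = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return render_frame(contour, spec)


class TestEsfDespeckle:
    def test_constant_image_unchanged(self):
        f = frame_of(np.full((32, 32), 7.0))
        out = esf_despeckle(f, n_iter=15)
        assert np.allclose(out.intensity, 7.0)

    def test_zero_iterations_is_identity(self):
        img = np.random.default_rng(0).random((24, 24))
        f = frame_of(img)
        assert np.array_equal(esf_despeckle(f, n_iter=0).intensity, img)

    def test_maximum_principle(self):
        img = np.random.default_rng(1).random((48, 48))
        out = esf_despeckle(frame_of(img), n_iter=20)
        assert out.intensity.max() <= img.max() + 1e-6
        assert out.intensity.min() >= img.min() - 1e-6

    def test_disk_boundary_shrinks_under_curve_shortening(self):
        # perimeter of the 0.5 level set must not increase
        n = 96
        c = (np.arange(n) - n / 2)[None, :]
        disk = (np.hypot(c, c.T) < 30).astype(float)

        def perim(img):
            return sum(
                np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1))
                for seg in measure.find_contours(img, 0.5)
            )

        out = esf_despeckle(frame_of(disk), n_iter=20, dt=0.2)
        assert perim(out.intensity) <= perim(disk) + 1e-6

    def test_invalid_dt_and_nonfinite_input_raise(self):
        with pytest.raises(SegmentationError):
            esf_despeckle(frame_of(np.zeros((8, 8))), dt=0.3)
        with pytest.raises(SegmentationError):
            frame_of(np.full((8, 8), np.nan))


class TestGaussianSmooth:
    def test_constant_unchanged_and_impulse_gives_kernel(self):
        assert np.allclose(gaussian_smooth(frame_of(np.full((16, 16), 3.0))).intensity, 3.0)
        imp = np.zeros((9, 9))
        imp[4, 4] = 1.0
        out = gaussian_smooth(frame_of(imp)).intensity
        expected = np.outer([1, 2, 1], [1, 2, 1]) / 16.0
        assert np.allclose(out[3:6, 3:6], expected)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)

    def test_noise_variance_decreases_and_sum_preserved(self):
        img = np.random.default_rng(2).random((64, 64))
        out = gaussian_smooth(frame_of(img)).intensity
        assert out.var() < img.var()
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)


class TestStarEdges:
    def test_ring_candidates_near_true_radius(self):
        frame = frame_of(ring_image(10.0))
        band = SearchBand(Ellipse(0, 0, 10, 10, 0), 2.0, 2.0)
        cands = star_edge_candidates(frame, band, n_rays=64)
        assert len(cands) == 64
        radii = np.array([np.hypot(*c.point) for c in cands])
        assert np.abs(radii - 10.0).max() < 0.5

    def test_flat_band_yields_no_candidates(self):
        frame = frame_of(np.full((128, 128), 0.4))
        band = SearchBand(Ellipse(0, 0, 10, 10, 0), 2.0, 2.0)
        assert star_edge_candidates(frame, band) == []

    def test_attenuated_lateral_sectors_drop_out(self):
        frame = frame_of(ring_image(10.0, attenuation=0.98))
        band = SearchBand(Ellipse(0, 0, 10, 10, 0), 2.0, 2.0)
        cands = star_edge_candidates(frame, band, n_rays=64, accept_fraction=0.5)
        thetas = np.array([c.theta for c in cands])
        # top/bottom rays (near +/- 90 deg) survive, lateral rays are culled
        assert np.any(np.abs(np.sin(thetas)) > 0.9)
        assert all(abs(np.cos(t)) < 0.95 for t in thetas)

    def test_band_outside_image_raises(self):
        frame = frame_of(np.zeros((64, 64)), spacing=0.1)  # 6.4 mm field
        band = SearchBand(Ellipse(0, 0, 5, 5, 0), 1.0, 1.0)
        with pytest.raises(SegmentationError):
            star_edge_candidates(frame, band)

    def test_every_candidate_lies_inside_the_band(self):
        frame = frame_of(ring_image(10.0))
        ref = Ellipse(0.4, -0.3, 10.5, 9.5, 0.2)
        band = SearchBand(ref, 2.0, 2.0)
        for c in star_edge_candidates(frame, band):
            r = np.hypot(*(c.point - ref.center))
            r_ref = ref.radius_at(c.theta)
            assert r_ref - band.inward - 0.11 <= r <= r_ref + band.outward + 0.11


class TestFitEllipse:
    def test_exact_recovery(self):
        e = Ellipse(3.0, -2.0, 20.0, 12.0, 0.4)
        f = fit_ellipse(e.sample(12))
        assert np.allclose(f.as_vector(), e.as_vector(), atol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(6.0, 30.0),
        ratio=st.floats(0.35, 0.99),
        phi=st.floats(0.0, 3.1),
        cx=st.floats(-10.0, 10.0),
        cy=st.floats(-10.0, 10.0),
    )
    def test_exact_recovery_property(self, a, ratio, phi, cx, cy):
        e = Ellipse(cx, cy, a, a * ratio, phi)
        f = fit_ellipse(e.sample(16))
        assert f.area == pytest.approx(e.area, rel=1e-6)
        assert np.allclose(f.center, e.center, atol=1e-6)

    def test_noisy_points_monte_carlo(self):
        # 0.2 mm point noise: parameters within 0.3 mm / 0.05 rad on average
        truth = Ellipse(3.0, -2.0, 20.0, 12.0, 0.4)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = truth.sample(40) + 0.2 * rng.standard_normal((40, 2))
            f = fit_ellipse(pts)
            errs.append(
                [
                    abs(f.cx - truth.cx), abs(f.cy - truth.cy),
                    abs(f.a - truth.a), abs(f.b - truth.b),
                    abs(f.phi - truth.phi),
                ]
            )
        med = np.median(errs, axis=0)
        assert np.all(med[:4] < 0.3)
        assert med[4] < 0.05

    def test_too_few_or_collinear_points_raise(self):
        with pytest.raises(EllipseFitError):
            fit_ellipse(np.array([[0, 0], [1, 0], [2, 0], [3, 0]]))
        line = np.column_stack([np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(EllipseFitError):
            fit_ellipse(line)


class TestKalman:
    def test_measurement_equal_to_prediction_keeps_state(self):
        e = Ellipse(0, 0, 10, 8, 0.3)
        s0 = TrackerState.initial(e)
        s1 = kalman_step(s0, e)
        assert np.allclose(s1.x, s0.x, atol=1e-12)
        assert np.trace(s1.P) < np.trace(s0.P + s0.Q)

    def test_zero_measurement_noise_returns_measurement(self):
        s0 = TrackerState.initial(Ellipse(0, 0, 10, 8, 0.3))
        meas = Ellipse(1.0, -0.5, 11.0, 7.5, 0.4)
        s1 = kalman_step(s0, meas, R=np.zeros((5, 5)))
        assert np.allclose(s1.ellipse.as_vector(), meas.as_vector(), atol=1e-9)

    def test_filtering_reduces_variance_of_jittered_track(self):
        truth = Ellipse(0, 0, 10, 9, 0.2)
        rng = np.random.default_rng(5)
        state = TrackerState.initial(truth)
        R = np.diag([0.5**2] * 4 + [0.05**2])
        raw, filt = [], []
        for _ in range(200):
            noisy = Ellipse.from_vector(
                truth.as_vector() + np.concatenate([0.5 * rng.standard_normal(4), [0.05 * rng.standard_normal()]])
            )
            state = kalman_step(state, noisy, R=R)
            raw.append(noisy.a)
            filt.append(state.ellipse.a)
        assert np.var(filt[20:]) < np.var(raw[20:])

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(SegmentationError):
            TrackerState(np.zeros(5), -np.eye(5), np.eye(5), np.eye(5))


class TestSegmentSweep:
    def test_single_frame_returns_fit_at_init(self):
        frame = frame_of(ring_image(10.0))
        out = segment_sweep([frame], Ellipse(0, 0, 10, 10, 0))
        assert len(out) == 1
        assert out[0].area == pytest.approx(np.pi * 100, rel=0.05)

    def test_band_thickness_per_vessel_class(self):
        ref = Ellipse(0, 0, 10, 10, 0)
        assert SearchBand.for_class(ref, "healthy").thickness == pytest.approx(2.5)
        assert SearchBand.for_class(ref, "aaa").thickness == pytest.approx(7.0)
        assert set(BAND_THICKNESS_MM) == {"healthy", "aaa"}

    def test_offset_init_converges_within_ten_frames(self):
        frame = frame_of(ring_image(10.0))
        frames = [
            BModeFrame(frame.intensity, frame.pixel_spacing, i, i / 25.0)
            for i in range(12)
        ]
        out = segment_sweep(frames, Ellipse(3.0, 0.0, 10, 10, 0), vessel_class="aaa")
        last = out[9]
        assert np.hypot(last.cx, last.cy) < 0.5
        assert np.sqrt(last.a * last.b) == pytest.approx(10.0, abs=0.3)

    def test_track_lost_after_consecutive_failures(self):
        good = frame_of(ring_image(10.0))
        flat = frame_of(np.full_like(good.intensity, 0.4))
        frames = [good] + [flat] * 12
        with pytest.warns(UserWarning):
            with pytest.raises(TrackLostError):
                segment_sweep(frames, Ellipse(0, 0, 10, 10, 0), max_consecutive_failures=5)

    def test_noiseless_sweep_area_error_under_two_percent(
        self, clean_sweep, segmented_sweep
    ):
        spec, frames, truth = clean_sweep
        areas = np.array([e.area for e in segmented_sweep])
        true_areas = np.pi * truth.radii**2
        assert (np.abs(areas - true_areas) / true_areas).max() < 0.02

    def test_fitted_area_series_is_periodic_at_heart_frequency(
        self, clean_sweep, segmented_sweep
    ):
        from scipy.signal import periodogram

        spec, frames, truth = clean_sweep
        areas = np.array([e.area for e in segmented_sweep])
        freqs, power = periodogram(areas - areas.mean(), fs=25.0, window="hann")
        # the slow bulge trend owns the lowest bins; the cardiac line must
        # dominate the physiological band
        band = freqs >= 0.5
        f_dom = freqs[band][np.argmax(power[band])]
        assert abs(f_dom - truth.heart_frequency) <= freqs[1] - freqs[0]
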