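"""Membrane tracer, circle fit, curvature statistic and population summaries."""

import numpy as np
import pytest

from guvshape import synthetic as syn
from guvshape import tracing as tr

from conftest import FRAME_PX, PIXEL_UM, RADIUS_UM


class TestAdaptiveThreshold:
    def test_uniform_image(self):
        img = np.full((128, 128), 50.0)
        assert tr.adaptive_threshold(img, (64, 64), (64, 100)) == 50.0

    def test_seed_at_origin_uses_extra_only(self):
        img = np.zeros((128, 128))
        img[54:75, 54:75] = 7.0  # covers the 20 px (-> 21 with centre) region
        assert tr.adaptive_threshold(img, (64, 64), (64, 64), extra=20) == pytest.approx(7.0)

    def test_guv_threshold_between_interior_and_peak(self, circle_frame):
        thr = tr.adaptive_threshold(circle_frame.pixels, (256, 256), (256, 356))
        assert 10.0 < thr < 205.0

    def test_degenerate_region_raises(self):
        img = np.zeros((128, 128))
        with pytest.raises(ValueError, match="degenerate"):
            tr.adaptive_threshold(img, (64, 64), (64, 64), extra=0)


class TestTraceCircle:
    def test_point_count_and_subpixel_accuracy(self, circle_frame, traced_circle):
        trace, circle, profile = traced_circle
        assert len(trace) == 120
        center = np.array([FRAME_PX / 2, FRAME_PX / 2])
        r_px = RADIUS_UM / PIXEL_UM
        vertex_err = np.abs(np.hypot(*(trace.vertices - center).T) - r_px)
        assert vertex_err.max() < 0.5
        # pixel points stay within the snapping bound of the true circle
        pixel_err = np.abs(np.hypot(*(trace.points - center).T) - r_px)
        assert pixel_err.max() < 1.0
        assert circle.radius == pytest.approx(r_px, abs=0.5)

    def test_points_lie_on_above_threshold_pixels(self, circle_frame, traced_circle):
        trace, _, _ = traced_circle
        for fit in trace.step_fits[::10]:
            r, c = fit.pixel
            assert circle_frame.pixels[r, c] > fit.threshold

    def test_consecutive_points_subtend_step_angle(self, traced_circle):
        trace, _, _ = traced_circle
        rel = trace.vertices - trace.origin
        ang = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
        steps = np.degrees(np.abs(np.diff(ang)))
        assert np.all(np.abs(steps - 3.0) < 1.5)

    def test_blank_image_fails_at_step_zero(self):
        with pytest.raises(tr.TraceError, match="step 0"):
            tr.trace_contour(np.zeros((128, 128)), x0=(64, 64), x_seed=(64, 100))

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            tr.TraceSettings(roi_size=20)
        with pytest.raises(ValueError):
            tr.TraceSettings(step_deg=7.0)


@pytest.fixture(scope="module")
def deformed_frame():
    shape = syn.make_contour(10.0, modes=[(3, 0.08, 0.5)])
    return syn.render_guv_slice(shape, syn.OpticsModel())


class TestEquivariance:
    def test_sdk_invariant_under_rot90_and_translation(self, deformed_frame):
        _, _, p0 = tr.trace_guv(deformed_frame.pixels)
        _, _, p90 = tr.trace_guv(np.rot90(deformed_frame.pixels))
        assert abs(p0.sd_k - p90.sd_k) < 0.002
        shifted = np.roll(deformed_frame.pixels, (7, -12), axis=(0, 1))
        _, _, pt = tr.trace_guv(shifted)
        assert abs(p0.sd_k - pt.sd_k) < 0.002

    def test_rot90_maps_traced_points(self, deformed_frame):
        t0, _, _ = tr.trace_guv(deformed_frame.pixels)
        t90, _, _ = tr.trace_guv(np.rot90(deformed_frame.pixels))
        n = deformed_frame.pixels.shape[1]
        # np.rot90 maps (r, c) -> (n-1-c, r); compare as unordered sets via
        # nearest-neighbour distance
        mapped = np.column_stack([n - 1 - t0.vertices[:, 1], t0.vertices[:, 0]])
        d = np.min(
            np.hypot(
                mapped[:, None, 0] - t90.vertices[None, :, 0],
                mapped[:, None, 1] - t90.vertices[None, :, 1],
            ),
            axis=1,
        )
        assert d.max() < 0.5


class TestCircleFit:
    def test_exact_circle_machine_precision(self):
        theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        pts = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta)])
        center, radius = tr.fit_circle_kasa(pts)
        assert np.allclose(center, 0, atol=1e-9)
        assert radius == pytest.approx(100.0, abs=1e-9)

    def test_equilateral_triangle_circumcircle(self):
        theta = np.array([0, 2 * np.pi / 3, 4 * np.pi / 3])
        pts = np.column_stack([3 + 50 * np.cos(theta), -2 + 50 * np.sin(theta)])
        center, radius = tr.fit_circle_kasa(pts)
        assert np.allclose(center, [3, -2], atol=1e-9)
        assert radius == pytest.approx(50.0, abs=1e-9)

    def test_ellipse_radius_bracketed_and_matches_objective_minimum(self):
        theta = np.linspace(0, 2 * np.pi, 240, endpoint=False)
        pts = np.column_stack([110 * np.cos(theta), 90 * np.sin(theta)])
        center, radius = tr.fit_circle_kasa(pts)
        assert 90.0 < radius < 110.0

        # brute-force check of the algebraic objective over a (c, R) grid
        def kasa_objective(cx, cy, r):
            return np.sum((np.sum((pts - [cx, cy]) ** 2, axis=1) - r**2) ** 2)

        best = kasa_objective(center[0], center[1], radius)
        rng = np.random.default_rng(0)
        for _ in range(300):
            dc = rng.normal(0, 2.0, size=3)
            assert kasa_objective(center[0] + dc[0], center[1] + dc[1], radius + dc[2]) >= best - 1e-6

    def test_collinear_points_raise(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            tr.fit_circle_kasa(pts)


class TestCurvature:
    def test_perfect_circle_profile(self):
        theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        pts = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta)])
        profile = tr.curvature_profile(pts)
        assert np.allclose(profile.k, 1.0, atol=1e-12)
        assert profile.sd_k == pytest.approx(0.0, abs=1e-12)
        assert not profile.deformed

    def test_threshold_semantics_strict_inequality(self):
        # radii alternating R(1 +/- d) give k alternating ~1 -/+ d: SD_k is
        # exactly the population SD of the two k values
        theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        r = 100 * (1 + 0.03 * (-1) ** np.arange(120))
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        circle = tr.ReferenceCircle(center=(0.0, 0.0), radius=100.0)
        profile = tr.curvature_profile(pts, circle=circle, threshold=0.026)
        assert profile.deformed  # SD_k ~ 0.03 > 0.026
        exact_sd = float(np.std(100.0 / r))
        at = tr.curvature_profile(pts, circle=circle, threshold=exact_sd)
        assert not at.deformed  # strictly-greater semantics at the boundary
        below = tr.curvature_profile(pts, circle=circle, threshold=exact_sd - 1e-12)
        assert below.deformed

    def test_zero_radius_point_raises(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        circle = tr.ReferenceCircle(center=(0.0, 0.0), radius=1.0)
        with pytest.raises(ValueError, match="R_i = 0"):
            tr.curvature_profile(pts, circle=circle)

    def test_pipeline_matches_analytic_oracle(self):
        shape = syn.make_contour(10.0, modes=[(2, 0.10, 0.0)])
        frame = syn.render_guv_slice(shape, syn.OpticsModel())
        _, _, profile = tr.trace_guv(frame.pixels)
        truth = shape.ground_truth_sd_k()
        assert abs(profile.sd_k - truth) <= max(0.05 * truth, 0.002)


class TestPopulation:
    def _profiles(self, amp, n, seed):
        rng = np.random.default_rng(seed)
        profiles = []
        for _ in range(n):
            shape = syn.make_contour(10.0, modes=[(2, amp, float(rng.uniform(0, 2 * np.pi)))] if amp else [])
            theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
            profiles.append(tr.curvature_profile(shape.points(theta)))
        return profiles

    def test_efficiency_is_deformed_fraction(self):
        mixed = self._profiles(0.10, 4, 0) + self._profiles(0.0, 6, 1)
        stats = tr.population_stats(mixed)
        assert stats.efficiency == pytest.approx(0.4)

    def test_all_undeformed_mass_at_unity(self):
        stats = tr.population_stats(self._profiles(0.0, 10, 2))
        assert stats.efficiency == 0.0
        centers = 0.5 * (stats.hist_edges[:-1] + stats.hist_edges[1:])
        assert centers[np.argmax(stats.hist_counts)] == pytest.approx(1.0, abs=0.02)

    def test_elongated_state_broadens_pooled_histogram(self):
        bare = tr.population_stats(self._profiles(0.0, 152, 3))
        deformed = tr.population_stats(self._profiles(0.10, 152, 4))
        pooled_sd = lambda s: np.concatenate([p.k for p in s]).std()  # noqa: E731
        bare_k = np.concatenate([p.k for p in self._profiles(0.0, 152, 3)])
        deformed_k = np.concatenate([p.k for p in self._profiles(0.10, 152, 4)])
        assert deformed_k.std() > bare_k.std()
        assert deformed.efficiency > bare.efficiency

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            tr.population_stats([])

    def test_baseline_calibration_recovers_mean(self):
        profiles = self._profiles(0.03, 20, 5)
        assert tr.calibrate_baseline(profiles) == pytest.approx(
            np.mean([p.sd_k for p in profiles])
        )
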