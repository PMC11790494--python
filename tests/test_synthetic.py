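"""Generator contracts: analytic shapes, renders, influx, FCS and binding."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from guvshape import synthetic as syn


class TestContourShape:
    def test_circle_has_constant_radius_and_zero_sdk(self):
        shape = syn.make_contour(10.0)
        theta = np.linspace(0, 2 * np.pi, 37)
        assert np.allclose(shape.r(theta), 10.0)
        assert shape.ground_truth_sd_k() < 1e-12

    def test_amplitude_sum_precondition(self):
        with pytest.raises(ValueError, match="self-intersection"):
            syn.make_contour(10.0, modes=[(3, 0.6, 0.0)])
        with pytest.raises(ValueError, match="self-intersection"):
            syn.make_contour(10.0, modes=[(2, 0.3, 0.0), (4, 0.25, 0.0)])

    def test_ground_truth_matches_geometric_circle_fit(self):
        """The Kasa-based oracle agrees with an independent geometric
        (orthogonal-residual) circle fit on a deformed contour."""
        shape = syn.make_contour(10.0, modes=[(2, 0.10, 0.0)])
        theta = np.linspace(0, 2 * np.pi, 3600, endpoint=False)
        pts = shape.points(theta)

        def resid(p):
            return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

        p = least_squares(resid, x0=[25.0, 25.0, 10.0]).x
        radii = np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1])
        sd_geometric = np.std(p[2] / radii)
        # the two objectives (algebraic vs orthogonal) give slightly
        # different reference circles; SD_k agrees at the sub-percent level
        assert shape.ground_truth_sd_k() == pytest.approx(sd_geometric, rel=0.01)

    def test_ground_truth_sdk_monotone_in_amplitude(self):
        amps = [0.01, 0.02, 0.05, 0.10, 0.15, 0.20]
        sdks = [syn.make_contour(10.0, modes=[(2, a, 0.0)]).ground_truth_sd_k() for a in amps]
        assert all(b > a for a, b in zip(sdks, sdks[1:]))


class TestRender:
    def test_ring_peak_and_interior_level(self):
        optics = syn.OpticsModel(interior_level=50.0, exterior_level=50.0, membrane_peak=200.0, background=5.0)
        frame = syn.render_guv_slice(syn.make_contour(10.0), optics)
        expected_peak = 5.0 + 50.0 + 200.0
        assert frame.pixels.max() == pytest.approx(expected_peak, rel=0.01)
        patch = frame.pixels[241:271, 241:271]
        assert patch.mean() == pytest.approx(55.0, abs=1e-6)  # noiseless: exact

    def test_noise_determinism_bit_identical(self):
        optics = syn.OpticsModel()
        noise = syn.NoiseModel(poisson_gain=2.0, gaussian_sd=3.0, seed=7)
        shape = syn.make_contour(10.0)
        a = syn.render_guv_slice(shape, optics, noise=noise)
        b = syn.render_guv_slice(shape, optics, noise=noise)
        assert np.array_equal(a.pixels, b.pixels)

    def test_ring_intensity_linear_in_membrane_peak(self):
        shape = syn.make_contour(10.0)
        totals = []
        for peak in (100.0, 200.0):
            optics = syn.OpticsModel(membrane_peak=peak, interior_level=0.0, exterior_level=0.0, background=0.0)
            totals.append(syn.render_guv_slice(shape, optics).pixels.sum())
        assert totals[1] == pytest.approx(2.0 * totals[0], rel=1e-9)

    def test_contour_exceeding_frame_names_required_size(self):
        shape = syn.make_contour(10.0, frame_size_px=128)
        with pytest.raises(ValueError, match=r"128 px frame.*needs >= \d+ px"):
            syn.render_guv_slice(shape, syn.OpticsModel(), size_px=128)

    def test_frame_validation(self):
        with pytest.raises(ValueError, match=">= 64"):
            syn.ImageFrame(pixels=np.zeros((32, 32)), pixel_size_um=0.1)
        with pytest.raises(ValueError, match="finite"):
            syn.ImageFrame(pixels=np.full((64, 64), np.nan), pixel_size_um=0.1)


class TestInflux:
    def test_closed_form_levels(self):
        sc = syn.PermeabilityScenario(rate_per_min=0.05, onset_min=100.0)
        level = syn.interior_level_at(np.array([130.0]), sc, exterior_level=100.0)[0]
        assert level == pytest.approx(100.0 * (1 - np.exp(-1.5)), rel=1e-12)
        # non-permeable and instant limits
        assert syn.interior_level_at(np.array([500.0]), syn.PermeabilityScenario(), 100.0)[0] == 0.0
        fast = syn.PermeabilityScenario(rate_per_min=1e6, onset_min=0.0)
        assert syn.interior_level_at(np.array([1.0]), fast, 100.0)[0] == pytest.approx(100.0)

    def test_bleach_event_rescales_then_relaxes(self):
        sc = syn.PermeabilityScenario(rate_per_min=0.1, onset_min=0.0, bleach_events=((10.0, 0.2),))
        t = np.array([10.0, 20.0])
        lv = syn.interior_level_at(t, sc, exterior_level=100.0)
        pre = 100.0 * (1 - np.exp(-1.0))
        post = pre * 0.2
        assert lv[0] == pytest.approx(post)
        assert lv[1] == pytest.approx(100.0 - (100.0 - post) * np.exp(-1.0))

    def test_ground_truth_series_and_errors(self):
        shape = syn.make_contour(10.0)
        optics = syn.OpticsModel(membrane_peak=0.0, interior_level=0.0, exterior_level=100.0, background=0.0)
        frames, truth = syn.simulate_influx_stack(shape, optics, syn.PermeabilityScenario(), [0.0, 10.0])
        assert np.allclose(truth.relative_import, 1.0)  # non-permeable, dark lumen
        with pytest.raises(ValueError, match="increasing"):
            syn.simulate_influx_stack(shape, optics, syn.PermeabilityScenario(), [10.0, 10.0])
        with pytest.raises(ValueError, match="non-negative"):
            syn.simulate_influx_stack(shape, optics, syn.PermeabilityScenario(), [-1.0, 5.0])


class TestCurvesAndSpectra:
    def test_fcs_curve_reproduces_model_exactly(self):
        lags = np.logspace(-6, 0, 64)
        curve = syn.generate_fcs_curve(10.0, 1e-3, lags)
        assert np.allclose(curve.g, 0.1 / (1 + lags / 1e-3), rtol=0, atol=1e-15)
        # half-amplitude at tau = tau_D; G(0+) -> 1/N
        half = syn.generate_fcs_curve(10.0, 1e-3, [1e-9, 1e-3]).g
        assert half[1] == pytest.approx(0.05, rel=1e-9)
        assert half[0] == pytest.approx(0.1, rel=1e-5)
        # direct evaluation at a printed lag
        g = syn.generate_fcs_curve(8.0, 2.59e-5, [1e-6, 1e-4]).g[1]
        assert g == pytest.approx((1 / 8) / (1 + 1e-4 / 2.59e-5), rel=1e-12)
        with pytest.raises(ValueError):
            syn.generate_fcs_curve(0.0, 1e-3)
        with pytest.raises(ValueError):
            syn.generate_fcs_curve(8.0, -1.0)

    def test_binding_series_values(self):
        t = np.array([0.0, 20.0, 2000.0])
        s = syn.generate_binding_series(100.0, 0.05, t)
        assert s.intensity[0] == 0.0
        assert s.intensity[1] == pytest.approx(100.0 * (1 - np.exp(-1.0)), rel=1e-12)
        assert s.intensity[2] == pytest.approx(100.0, rel=1e-6)

    def test_generator_determinism(self):
        a = syn.generate_fcs_curve(8.0, 1e-4, noise_sd=0.01, seed=3)
        b = syn.generate_fcs_curve(8.0, 1e-4, noise_sd=0.01, seed=3)
        assert np.array_equal(a.g, b.g)
        s1 = syn.generate_binding_series(10.0, 0.1, [1, 2, 3], noise_sd=1.0, seed=4)
        s2 = syn.generate_binding_series(10.0, 0.1, [1, 2, 3], noise_sd=1.0, seed=4)
        assert np.array_equal(s1.intensity, s2.intensity)

    def test_fret_spectra_states(self):
        df = syn.generate_fret_spectra({"s-DR": 7.2, "e-DR": 3.1})
        assert set(df["state"]) == {"s-DR", "e-DR"}
        # close dyes emit mostly in the acceptor band
        edr = df[df.state == "e-DR"]
        acceptor = edr[(edr.wavelength_nm > 660) & (edr.wavelength_nm < 680)].intensity.sum()
        donor = edr[(edr.wavelength_nm > 560) & (edr.wavelength_nm < 580)].intensity.sum()
        assert acceptor > donor


def test_tiff_roundtrip(tmp_path):
    shape = syn.make_contour(3.0, frame_size_px=128)
    optics = syn.OpticsModel()
    frames = [
        syn.render_guv_slice(shape, optics, size_px=128, time_min=t) for t in (0.0, 5.0)
    ]
    path = tmp_path / "stack.tif"
    syn.save_tiff_stack(frames, path, ground_truth={"sd_k": 0.0})
    loaded = syn.load_tiff_stack(path)
    assert len(loaded) == 2
    assert loaded[0].pixel_size_um == pytest.approx(0.1)
    assert loaded[1].time == pytest.approx(5.0)
    assert np.allclose(loaded[0].pixels, frames[0].pixels, atol=1e-4)
    assert (tmp_path / "stack.json").exists()
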