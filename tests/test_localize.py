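"""Background estimation, signal detection and centre-of-mass localization."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from tjmesh.localize import (
    BackgroundModel,
    FrameStack,
    SignalROI,
    detect_signals,
    estimate_background,
    localize_center_of_mass,
    localize_stack,
)


def _stack(frames, px=100.0):
    return FrameStack(np.asarray(frames, dtype=float), px)


class TestBackground:
    def test_constant_stack_is_fixed_point(self):
        stack = _stack(np.full((5, 8, 8), 100.0))
        for s in (0.1, 0.5, 1.0):
            model = estimate_background(stack, smoothing=s)
            np.testing.assert_allclose(model.background, 100.0)

    def test_smoothing_one_tracks_last_frame(self):
        frames = np.stack([np.full((4, 4), v) for v in (10.0, 50.0, 90.0)])
        model = estimate_background(_stack(frames), smoothing=1.0)
        np.testing.assert_allclose(model.background, 90.0)

    def test_two_frame_recursion(self):
        frames = np.stack([np.zeros((3, 3)), np.full((3, 3), 10.0)])
        model = estimate_background(_stack(frames), smoothing=0.5)
        np.testing.assert_allclose(model.background, 5.0)

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            estimate_background(_stack(np.empty((0, 4, 4))))

    def test_noise_width_is_poisson(self):
        model = BackgroundModel(np.array([[0.25, 100.0]]), 0.1)
        np.testing.assert_allclose(model.noise_width, [[1.0, 10.0]])


class TestDetection:
    def test_flat_frame_yields_nothing(self):
        bg = BackgroundModel(np.full((16, 16), 100.0), 0.1)
        assert detect_signals(np.full((16, 16), 100.0), bg) == []

    def test_single_bright_pixel_centres_roi(self):
        bg = BackgroundModel(np.full((16, 16), 100.0), 0.1)
        frame = np.full((16, 16), 100.0)
        frame[8, 9] += 100.0 * np.sqrt(100.0)  # 100 sigma above background
        rois = detect_signals(frame, bg, n_sigma=4.0, roi_half=3)
        assert len(rois) == 1
        assert (rois[0].i0, rois[0].j0) == (5, 6)

    def test_nearby_maxima_are_both_discarded(self):
        # two maxima 3 px apart fall inside one 7x7 window: optical
        # isolation cannot be guaranteed, so both candidates are dropped
        bg = BackgroundModel(np.full((24, 24), 100.0), 0.1)
        frame = np.full((24, 24), 100.0)
        frame[10, 10] += 500.0
        frame[10, 13] += 480.0
        assert detect_signals(frame, bg, n_sigma=4.0, roi_half=3) == []

    def test_border_candidates_dropped(self):
        bg = BackgroundModel(np.full((16, 16), 100.0), 0.1)
        frame = np.full((16, 16), 100.0)
        frame[1, 1] += 500.0
        assert detect_signals(frame, bg, n_sigma=4.0, roi_half=3) == []


def _roi_from_values(values, i0=0, j0=0, noise=0.0):
    values = np.asarray(values, dtype=float)
    return SignalROI(0, i0, j0, values, np.full_like(values, noise))


class TestCenterOfMass:
    def test_symmetric_spot_lands_on_geometric_centre(self):
        vals = np.array([[1.0, 1.0, 1.0], [1.0, 8.0, 1.0], [1.0, 1.0, 1.0]])
        rec = localize_center_of_mass(_roi_from_values(vals), pixel_size=100.0)
        assert rec["x_nm"] == pytest.approx(150.0)
        assert rec["y_nm"] == pytest.approx(150.0)

    def test_point_signal_has_zero_width(self):
        vals = np.zeros((3, 3))
        vals[1, 2] = 50.0
        rec = localize_center_of_mass(_roi_from_values(vals), pixel_size=100.0)
        assert rec["x_nm"] == pytest.approx(250.0)
        assert rec["sigma_nm"] == 0.0
        assert rec["photons"] == pytest.approx(50.0)

    def test_all_noise_rejected(self):
        vals = np.full((3, 3), 2.0)
        roi = _roi_from_values(vals, noise=5.0)
        assert localize_center_of_mass(roi, pixel_size=100.0, corner_floor=1.0) is None

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 10, (5, 5))
        r1 = localize_center_of_mass(_roi_from_values(vals, i0=0, j0=0), 100.0)
        r2 = localize_center_of_mass(_roi_from_values(vals, i0=1, j0=1), 100.0)
        assert r2["x_nm"] - r1["x_nm"] == pytest.approx(100.0)
        assert r2["y_nm"] - r1["y_nm"] == pytest.approx(100.0)

    def test_accuracy_scales_inverse_sqrt_photons(self):
        # noiseless symmetric spot: sigma_loc = spot width / sqrt(Q)
        def spot(scale):
            g = np.exp(-0.5 * ((np.arange(7) - 3.0) / 1.2) ** 2)
            return scale * np.outer(g, g)

        r1 = localize_center_of_mass(_roi_from_values(spot(10.0)), 100.0)
        r4 = localize_center_of_mass(_roi_from_values(spot(40.0)), 100.0)
        assert r4["sigma_nm"] == pytest.approx(r1["sigma_nm"] / 2.0, rel=1e-9)

    def test_rmse_competitive_with_gaussian_fit(self):
        """Centre-of-mass error within 1.5x of a least-squares Gaussian fit
        on the same Poisson-noise ROIs (sigma_psf 120 nm, 1000 photons)."""
        rng = np.random.default_rng(17)
        px, spsf, photons, bg = 100.0, 120.0, 1000.0, 20.0
        grid = (np.arange(7) + 0.5) * px

        def model(xy, x0, y0, amp):
            gx = np.exp(-0.5 * ((grid - x0) / spsf) ** 2)
            gy = np.exp(-0.5 * ((grid - y0) / spsf) ** 2)
            return (amp * np.outer(gy, gx)).ravel()

        err_com, err_fit = [], []
        for _ in range(100):
            x0, y0 = rng.uniform(300, 400, 2)
            clean = bg + model(None, x0, y0, photons * px**2 / (2 * np.pi * spsf**2)).reshape(7, 7)
            noisy = rng.poisson(clean).astype(float)
            roi = SignalROI(0, 0, 0, noisy - bg, np.full((7, 7), np.sqrt(bg)))
            rec = localize_center_of_mass(roi, px, corner_floor=1.0)
            err_com.append(np.hypot(rec["x_nm"] - x0, rec["y_nm"] - y0))
            try:
                popt, _ = curve_fit(model, None, (noisy - bg).ravel(),
                                    p0=(350.0, 350.0, noisy.max() - bg))
                err_fit.append(np.hypot(popt[0] - x0, popt[1] - y0))
            except RuntimeError:
                err_fit.append(np.nan)
        rmse_com = np.sqrt(np.mean(np.square(err_com)))
        rmse_fit = np.sqrt(np.nanmean(np.square(err_fit)))
        assert rmse_com <= 1.5 * rmse_fit


class TestStackPipeline:
    def test_localizes_within_reported_accuracy(self):
        from tjmesh.io import LocalizationTable
        from tjmesh.simulate import simulate_frames

        rng = np.random.default_rng(23)
        n = 60
        truth = LocalizationTable.from_arrays(
            rng.uniform(1000, 7000, n), rng.uniform(1000, 7000, n),
            frame=np.arange(1, n + 1), photons=np.full(n, 1200.0),
            sigma_loc=np.full(n, 20.0),
        )
        stack, truth = simulate_frames(truth, pixel_size=100.0, psf_sigma=130.0,
                                       background=10.0, rng=rng)
        table, _ = localize_stack(stack, smoothing=0.2, n_sigma=5.0)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(table.xy).query(truth.xy)
        # median position error bounded by twice the reported accuracy
        assert np.median(d) <= 2.0 * np.median(table.sigma_loc)
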