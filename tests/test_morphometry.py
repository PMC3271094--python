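"""Radial profiles, contour extraction/correction and shape descriptors."""

import numpy as np
import pytest

from tjmesh.io import LocalizationTable
from tjmesh.morphometry import (
    MeshAnalysisError,
    MeshContour,
    NoMeshError,
    correct_contour,
    diameter_from_circumference,
    estimate_mean_radius,
    extract_contour,
    feret_ratio,
    measure_mesh,
    network_axis,
    orientation_ratio,
    partition_counts,
    profile_peak_intensity,
    radial_profile,
    strand_band_and_interior,
)
from tjmesh.render import RenderedImage, adaptive_blur_render

from conftest import annulus_table


def _ring_image(radius=200.0, width=20.0, side=1000.0, px=2.0, value=1.0):
    n = int(side / px)
    c = side / 2.0
    xs = (np.arange(n) + 0.5) * px
    rr = np.hypot(xs[None, :] - c, xs[:, None] - c)
    data = np.where(np.abs(rr - radius) <= width / 2.0, value, 0.0)
    return RenderedImage(data, px, (0.0, 0.0)), (c, c)


def _circle_contour(radius=200.0, center=(500.0, 500.0), n=360):
    t = np.linspace(0, 2 * np.pi, n + 1)[:-1]
    return MeshContour(
        np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])
    )


def _ellipse_contour(a, b, center=(0.0, 0.0), theta=0.0, n=720):
    t = np.linspace(0, 2 * np.pi, n + 1)[:-1]
    ex, ey = a * np.cos(t), b * np.sin(t)
    c, s = np.cos(theta), np.sin(theta)
    return MeshContour(
        np.column_stack([center[0] + c * ex - s * ey, center[1] + s * ex + c * ey])
    )


class TestRadialProfile:
    def test_uniform_ring_peaks_at_its_radius(self):
        img, center = _ring_image(radius=200.0, width=20.0)
        prof = radial_profile(img, center, bin_width=4.0, r_max=400.0)
        peak_bin = np.nanargmax(prof.intensity)
        assert 190.0 <= prof.r[peak_bin] <= 210.0

    def test_uniform_image_is_flat(self):
        img = RenderedImage(np.ones((400, 400)), 2.0, (0.0, 0.0))
        prof = radial_profile(img, (400.0, 400.0), bin_width=4.0, r_max=300.0)
        v = prof.intensity[np.isfinite(prof.intensity)]
        assert v.max() / v.min() <= 1.05

    def test_two_concentric_rings_give_two_maxima(self):
        img1, center = _ring_image(radius=150.0, width=20.0, side=1200.0)
        img2, _ = _ring_image(radius=400.0, width=20.0, side=1200.0)
        img = RenderedImage(img1.data + img2.data, 2.0, (0.0, 0.0))
        prof = radial_profile(img, (600.0, 600.0), bin_width=4.0, r_max=550.0)
        y = np.nan_to_num(prof.intensity)
        maxima = [
            prof.r[i]
            for i in range(1, len(y) - 1)
            if y[i] >= y[i - 1] and y[i] >= y[i + 1] and y[i] > 0.5 * y.max()
        ]
        assert any(abs(m - 150.0) <= 8.0 for m in maxima)
        assert any(abs(m - 400.0) <= 8.0 for m in maxima)

    def test_center_outside_image_raises(self):
        img = RenderedImage(np.ones((100, 100)), 2.0, (0.0, 0.0))
        with pytest.raises(MeshAnalysisError):
            radial_profile(img, (500.0, 50.0))


class TestMeanRadius:
    def _profile(self, y, bin_width=4.0):
        from tjmesh.morphometry import RadialProfile

        y = np.asarray(y, dtype=float)
        r = (np.arange(len(y)) + 0.5) * bin_width
        return RadialProfile(r, y, np.ones(len(y), dtype=int), bin_width)

    def test_gaussian_bump_recovered_to_half_bin(self):
        r = (np.arange(100) + 0.5) * 4.0
        prof = self._profile(np.exp(-0.5 * ((r - 200.0) / 30.0) ** 2))
        assert estimate_mean_radius(prof) == pytest.approx(200.0, abs=2.0)

    def test_monotone_profile_raises(self):
        with pytest.raises(NoMeshError):
            estimate_mean_radius(self._profile(np.linspace(0, 1, 50)))

    def test_noisy_ring_within_ten_percent(self):
        rng = np.random.default_rng(8)
        r = (np.arange(100) + 0.5) * 4.0
        clean = np.exp(-0.5 * ((r - 200.0) / 30.0) ** 2)
        noisy = clean + rng.normal(0, 0.2, len(r))  # SNR 5
        assert estimate_mean_radius(self._profile(noisy)) == pytest.approx(200.0, rel=0.10)


class TestContourExtraction:
    def test_synthetic_circular_mesh_contour(self):
        table = annulus_table(radius=200.0, width=10.0, n=3000, seed=1, sigma_loc=20.0)
        # rendered with realistic scatter applied to the positions
        rng = np.random.default_rng(2)
        xy = table.xy + rng.normal(0, 20.0, (len(table), 2))
        scat = LocalizationTable.from_arrays(xy[:, 0], xy[:, 1], sigma_loc=np.full(len(table), 20.0))
        img = adaptive_blur_render(scat, pixel_size=2.0, sigma_floor=10.0)
        prof = radial_profile(img, (1000.0, 1000.0), r_max=450.0)
        r = estimate_mean_radius(prof)
        raw = extract_contour(img, (1000.0, 1000.0), r, norm_scale=profile_peak_intensity(prof))
        assert raw.contains(1000.0, 1000.0)
        assert raw.circumference == pytest.approx(2 * np.pi * 200.0, rel=0.15)

    def test_blank_roi_raises(self):
        img = RenderedImage(np.zeros((500, 500)), 2.0, (0.0, 0.0))
        with pytest.raises(MeshAnalysisError):
            extract_contour(img, (500.0, 500.0), 100.0)

    def test_elliptical_mesh_axis_ratio(self):
        rng = np.random.default_rng(3)
        n = 4000
        t = rng.uniform(0, 2 * np.pi, n)
        x = 1000.0 + 300.0 * np.cos(t) + rng.normal(0, 10.0, n)
        y = 1000.0 + 210.0 * np.sin(t) + rng.normal(0, 10.0, n)
        table = LocalizationTable.from_arrays(x, y, sigma_loc=np.full(n, 10.0))
        m = measure_mesh(table, (1000.0, 1000.0))
        assert m.feret_ratio == pytest.approx(0.7, abs=0.05)


class TestContourCorrection:
    def test_points_on_contour_leave_it_unchanged(self):
        raw = _circle_contour(200.0)
        rng = np.random.default_rng(4)
        t = rng.uniform(0, 2 * np.pi, 500)
        table = LocalizationTable.from_arrays(
            500.0 + 200.0 * np.cos(t), 500.0 + 200.0 * np.sin(t),
            sigma_loc=np.full(500, 1e-3),
        )
        out = correct_contour(raw, table, center=(500.0, 500.0), r_mean=200.0)
        assert out.corrected
        assert abs(out.offset_nm) <= 1.0
        assert out.circumference == pytest.approx(2 * np.pi * 200.0, rel=0.01)

    def test_constant_outside_offset_grows_circumference(self):
        raw = _circle_contour(200.0)
        rng = np.random.default_rng(5)
        t = rng.uniform(0, 2 * np.pi, 800)
        table = LocalizationTable.from_arrays(
            500.0 + 225.0 * np.cos(t), 500.0 + 225.0 * np.sin(t),
            sigma_loc=np.full(800, 1e-3),
        )
        out = correct_contour(raw, table, center=(500.0, 500.0), r_mean=200.0)
        assert out.offset_nm == pytest.approx(25.0, abs=2.0)
        assert out.circumference - raw.circumference == pytest.approx(2 * np.pi * 25.0, rel=0.10)

    def test_too_few_points_flagged_uncorrected(self):
        raw = _circle_contour(200.0)
        table = LocalizationTable.from_arrays([500.0], [700.0])
        out = correct_contour(raw, table, center=(500.0, 500.0))
        assert not out.corrected
        assert "uncorrected" in out.flags

    def test_full_synthetic_mesh_corrected_within_five_percent(self):
        table = annulus_table(radius=200.0, width=10.0, n=2500, seed=6, sigma_loc=1e-3)
        m = measure_mesh(table, (1000.0, 1000.0))
        assert m.diameter_nm == pytest.approx(400.0, rel=0.05)


class TestDiameter:
    @pytest.mark.parametrize(
        "circumference,expected",
        [(np.pi * 100.0, 100.0), (400.0, 400.0 / np.pi), (np.pi, 1.0)],
    )
    def test_examples(self, circumference, expected):
        assert diameter_from_circumference(circumference) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            diameter_from_circumference(0.0)


class TestBandAndInterior:
    def test_circle_band_area_is_annulus(self):
        contour = _circle_contour(200.0, n=2000)
        regions = strand_band_and_interior(contour, 25.0)
        exact = np.pi * (225.0**2 - 175.0**2) / 1e6
        assert regions.band_area_um2 == pytest.approx(exact, rel=1e-3)

    def test_tiny_mesh_loses_interior(self):
        contour = _circle_contour(20.0)
        regions = strand_band_and_interior(contour, 25.0)
        assert regions.interior is None

    def test_partition_is_exact(self):
        rng = np.random.default_rng(7)
        contour = _circle_contour(200.0)
        n = 2000
        table = LocalizationTable.from_arrays(
            rng.uniform(200, 800, n), rng.uniform(200, 800, n)
        )
        regions = strand_band_and_interior(contour, 25.0)
        n_band, n_int, n_ext = partition_counts(regions, table)
        assert n_band + n_int + n_ext == n

    def test_density_arithmetic(self):
        # 37 points over 0.01 um^2 of band is 3700 per um^2
        contour = _circle_contour(200.0, n=3000)
        regions = strand_band_and_interior(contour, 25.0)
        from tjmesh.morphometry import strand_density

        rng = np.random.default_rng(8)
        t = rng.uniform(0, 2 * np.pi, 37)
        table = LocalizationTable.from_arrays(
            500.0 + 200.0 * np.cos(t), 500.0 + 200.0 * np.sin(t)
        )
        expected = 37.0 / regions.band_area_um2
        assert strand_density(table, regions) == pytest.approx(expected)


class TestFeret:
    def test_circle_is_one(self):
        assert feret_ratio(_circle_contour(150.0)) == pytest.approx(1.0, abs=1e-3)

    def test_axis_aligned_ellipse(self):
        assert feret_ratio(_ellipse_contour(300.0, 210.0)) == pytest.approx(0.70, abs=0.002)

    def test_rotation_invariance(self):
        base = _ellipse_contour(300.0, 210.0)
        rot = _ellipse_contour(300.0, 210.0, theta=np.deg2rad(37.0))
        assert feret_ratio(rot) == pytest.approx(feret_ratio(base), abs=1e-3)

    def test_degenerate_collinear_raises(self):
        verts = np.column_stack([np.linspace(0, 100, 10), np.zeros(10)])
        with pytest.raises(ValueError):
            feret_ratio(MeshContour(verts))


class TestNetworkAxis:
    def test_horizontal_line(self):
        x = np.linspace(0, 1000, 50)
        axis = network_axis(LocalizationTable.from_arrays(x, np.zeros(50)))
        assert abs(axis.direction @ [1.0, 0.0]) == pytest.approx(1.0)
        assert axis.reliable

    def test_diagonal_line(self):
        x = np.linspace(0, 1000, 50)
        axis = network_axis(LocalizationTable.from_arrays(x, x))
        assert abs(axis.direction @ [np.sqrt(0.5), np.sqrt(0.5)]) == pytest.approx(1.0)

    def test_anisotropic_cloud_within_two_degrees(self):
        rng = np.random.default_rng(9)
        n = 10000
        table = LocalizationTable.from_arrays(
            rng.normal(0, 300.0, n), rng.normal(0, 100.0, n)
        )
        axis = network_axis(table)
        angle = np.degrees(np.arctan2(axis.direction[1], axis.direction[0]))
        assert abs(angle) <= 2.0

    def test_isotropic_cloud_flagged(self):
        rng = np.random.default_rng(10)
        n = 20000
        table = LocalizationTable.from_arrays(rng.normal(0, 100, n), rng.normal(0, 100, n))
        assert not network_axis(table).reliable


class TestOrientationRatio:
    def test_circle_is_one_for_any_axis(self):
        c = _circle_contour(150.0)
        from tjmesh.morphometry import NetworkAxis

        for ang in (0.0, 30.0, 77.0):
            v = np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))])
            assert orientation_ratio(c, v) == pytest.approx(1.0, abs=1e-3)

    def test_aligned_ellipse(self):
        c = _ellipse_contour(242.0, 200.0)
        assert orientation_ratio(c, np.array([1.0, 0.0])) == pytest.approx(1.21, abs=0.005)

    def test_perpendicular_axis_gives_reciprocal(self):
        c = _ellipse_contour(242.0, 200.0)
        assert orientation_ratio(c, np.array([0.0, 1.0])) == pytest.approx(1 / 1.21, abs=0.005)


class TestEndToEnd:
    def test_noise_free_circle_oracle(self):
        """Corrected diameter of a noise-free 10nm-strand circle within one
        render pixel plus one profile bin of the truth."""
        table = annulus_table(radius=200.0, width=10.0, n=2000, seed=42)
        m = measure_mesh(table, (1000.0, 1000.0))
        assert m.diameter_nm == pytest.approx(400.0, abs=2.0 + 4.0)

    def test_rigid_motion_invariance_on_clean_mesh(self):
        table = annulus_table(radius=180.0, width=10.0, n=2500, seed=11)
        m1 = measure_mesh(table, (1000.0, 1000.0))
        th = np.deg2rad(37.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = table.xy @ R.T + np.array([3000.0, 1500.0])
        t2 = LocalizationTable.from_arrays(xy[:, 0], xy[:, 1], sigma_loc=table.sigma_loc)
        seed2 = tuple(R @ np.array([1000.0, 1000.0]) + np.array([3000.0, 1500.0]))
        m2 = measure_mesh(t2, seed2)
        assert m2.diameter_nm == pytest.approx(m1.diameter_nm, rel=0.01)
        assert m2.area_um2 == pytest.approx(m1.area_um2, rel=0.01)
        assert m2.feret_ratio == pytest.approx(m1.feret_ratio, rel=0.01)

    def test_monotone_in_true_diameter(self, ladder_run):
        from scipy.stats import spearmanr

        meshes, table = ladder_run
        truths, measured = [], []
        for mesh in meshes:
            try:
                m = measure_mesh(table, mesh.center)
            except MeshAnalysisError:
                continue
            truths.append(mesh.diameter)
            measured.append(m.diameter_nm)
        assert len(measured) >= 18
        rho = spearmanr(truths, measured).statistic
        assert rho > 0.99

    def test_seed_outside_extent_raises_tagged_error(self):
        table = annulus_table()
        with pytest.raises(MeshAnalysisError) as exc:
            measure_mesh(table, (1e6, 1e6))
        assert exc.value.reason == "seed_outside"
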