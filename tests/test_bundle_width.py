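"""Bundle width pipeline: orientation, density ridge, distances, FWHM."""

import numpy as np
import pytest

from nanometrics.bundle_width import (
    FWHM_FACTOR,
    BundleROI,
    UnresolvableWidthError,
    compute_density_map,
    correct_for_precision,
    fit_centerline,
    fit_orientation,
    fit_width_profile,
    measure_bundle_width,
    perpendicular_distances,
)
from nanometrics.loc_io import LocalizationTable
from nanometrics.synthetic import BundleSpec, simulate_bundle_localizations


class TestOrientation:
    def test_diagonal_line_is_45_degrees(self):
        t = np.linspace(0, 100, 50)
        assert np.rad2deg(fit_orientation(t, t)) == pytest.approx(45.0)

    def test_horizontal_with_noise(self, rng):
        x = rng.uniform(0, 2000, 5000)
        y = rng.normal(0, 30, 5000)
        assert abs(np.rad2deg(fit_orientation(x, y))) < 1.0

    def test_rotation_equivariance(self, rng):
        x = rng.uniform(0, 2000, 2000)
        y = rng.normal(0, 30, 2000)
        base = fit_orientation(x, y)
        th = np.deg2rad(20.0)
        xr = x * np.cos(th) - y * np.sin(th)
        yr = x * np.sin(th) + y * np.cos(th)
        rotated = fit_orientation(xr, yr)
        diff = (rotated - base - th + np.pi / 2) % np.pi - np.pi / 2
        assert abs(np.rad2deg(diff)) < 1e-6

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_orientation(np.array([0.0]), np.array([0.0]))


class TestDensityMap:
    def test_single_event_is_gaussian_bump(self):
        dm = compute_density_map(np.array([500.0]), np.array([500.0]))
        r, c = np.unravel_index(np.argmax(dm.values), dm.values.shape)
        assert dm.x_coords()[c] == pytest.approx(500.0, abs=dm.grid_pitch_nm)
        assert dm.y_coords()[r] == pytest.approx(500.0, abs=dm.grid_pitch_nm)
        # total mass = 1 event
        assert dm.values.sum() * dm.grid_pitch_nm**2 == pytest.approx(1.0, rel=0.01)

    def test_superposition_mass_of_two_events(self):
        dm = compute_density_map(
            np.array([0.0, 2000.0]), np.array([0.0, 0.0])
        )
        assert dm.values.sum() * dm.grid_pitch_nm**2 == pytest.approx(2.0, rel=0.01)

    def test_column_argmax_matches_direct_kde_oracle(self, rng):
        n = 3000
        x = rng.uniform(0, 800, n)
        y = rng.normal(200, 40, n)
        sigma, pitch = 60.0, 20.0
        dm = compute_density_map(x, y, kernel_sigma_nm=sigma, grid_pitch_nm=pitch)
        gx, gy = dm.x_coords(), dm.y_coords()
        # brute-force direct-sum KDE on the same grid
        kde = np.zeros_like(dm.values)
        for r in range(len(gy)):
            d2 = (gx[None, :] - x[:, None]) ** 2 + (gy[r] - y)[:, None] ** 2
            kde[r] = np.exp(-0.5 * d2 / sigma**2).sum(axis=0)
        mid = (gx > 100) & (gx < 700)  # interior columns
        impl = np.argmax(dm.values[:, mid], axis=0)
        oracle = np.argmax(kde[:, mid], axis=0)
        assert np.abs(impl - oracle).max() <= 1

    def test_out_of_range_kernel_needs_flag(self):
        with pytest.raises(ValueError):
            compute_density_map(np.array([0.0]), np.array([0.0]), kernel_sigma_nm=20.0)
        compute_density_map(
            np.array([0.0]), np.array([0.0]),
            kernel_sigma_nm=20.0, allow_out_of_range=True,
        )


class TestCenterline:
    def _density_from(self, x, y):
        return compute_density_map(x, y, kernel_sigma_nm=60.0, grid_pitch_nm=10.0)

    def test_straight_bundle_recovered(self, rng):
        x = rng.uniform(0, 2000, 20_000)
        y = rng.normal(100.0, 30.0, 20_000)
        fit = fit_centerline(self._density_from(x, y), degree=3)
        xs = np.linspace(200, 1800, 50)
        rms = np.sqrt(np.mean((fit(xs) - 100.0) ** 2))
        assert rms < 2.0
        # higher-order terms contribute nothing: the curve stays flat
        assert np.abs(fit(xs) - 100.0).max() < 3.0

    def test_curved_parabola_recovered(self, rng):
        x = rng.uniform(0, 2000, 30_000)
        y_true = 1e-4 * x**2
        y = y_true + rng.normal(0, 25, len(x))
        fit = fit_centerline(self._density_from(x, y), degree=3)
        xs = np.linspace(200, 1800, 100)
        assert np.abs(fit(xs) - 1e-4 * xs**2).max() < 10.0  # within 1 cell

    def test_flat_density_has_no_ridge(self):
        from nanometrics.bundle_width import DensityMap

        flat = DensityMap(
            values=np.ones((50, 80)),
            grid_pitch_nm=10.0,
            kernel_sigma_nm=60.0,
            origin_nm=(0.0, 0.0),
        )
        with pytest.raises(ValueError, match="ridge"):
            fit_centerline(flat)


class TestPerpendicularDistances:
    def _line_fit(self):
        from nanometrics.bundle_width import CenterlineFit

        return CenterlineFit(
            theta_rad=0.0,
            pivot_nm=(0.0, 0.0),
            coeffs=np.array([0.0]),
            domain_nm=(-1000.0, 1000.0),
        )

    def test_point_above_line(self):
        d, dropped = perpendicular_distances(
            np.array([0.0]), np.array([5.0]), self._line_fit()
        )
        assert d[0] == pytest.approx(5.0)
        assert dropped == 0

    def test_point_on_curve_is_zero(self):
        d, _ = perpendicular_distances(
            np.array([10.0]), np.array([0.0]), self._line_fit()
        )
        assert abs(d[0]) < 1e-9

    def test_sign_flips_below_line(self):
        d, _ = perpendicular_distances(
            np.array([0.0]), np.array([-7.0]), self._line_fit()
        )
        assert d[0] == pytest.approx(-7.0)

    def test_cubic_matches_dense_sampling_oracle(self, rng):
        from nanometrics.bundle_width import CenterlineFit

        coeffs = np.array([50.0, 0.1, -2e-4, 8e-8])
        fit = CenterlineFit(
            theta_rad=0.0,
            pivot_nm=(0.0, 0.0),
            coeffs=coeffs,
            domain_nm=(0.0, 2000.0),
        )
        x = rng.uniform(200, 1800, 300)
        y = np.polynomial.polynomial.polyval(x, coeffs) + rng.normal(0, 60, 300)
        d, dropped = perpendicular_distances(x, y, fit)
        # brute force: 10^5 curve samples, chunked exhaustive search
        ts = np.linspace(0.0, 2000.0, 100_000)
        cy = np.polynomial.polynomial.polyval(ts, coeffs)
        kept = np.flatnonzero(np.ones(len(x), dtype=bool))
        oracle = []
        keep_flags = []
        for xi, yi in zip(x, y):
            dist2 = (ts - xi) ** 2 + (cy - yi) ** 2
            j = int(np.argmin(dist2))
            keep_flags.append(0 < j < len(ts) - 1)
            oracle.append(np.sqrt(dist2[j]))
        keep_flags = np.array(keep_flags)
        oracle = np.array(oracle)[keep_flags]
        assert dropped == int((~keep_flags).sum())
        np.testing.assert_allclose(np.abs(d), oracle, atol=0.1)


class TestWidthProfile:
    def test_gaussian_sigma_recovered(self, rng):
        d = rng.normal(0.0, 30.0, 100_000)
        _, _, fit = fit_width_profile(d)
        assert fit.sigma_nm == pytest.approx(30.0, abs=1.0)
        assert abs(fit.center_nm) < 1.0

    def test_degenerate_identical_distances_raise(self):
        with pytest.raises(ValueError):
            fit_width_profile(np.full(100, 5.0))

    def test_background_mixture_with_baseline(self, rng):
        core = rng.normal(0.0, 30.0, 19_000)
        bg = rng.uniform(-200, 200, 1000)
        _, _, fit = fit_width_profile(
            np.concatenate([core, bg]), baseline=True
        )
        assert fit.sigma_nm == pytest.approx(30.0, rel=0.05)
        assert fit.baseline > 0


class TestPrecisionCorrection:
    def test_quadrature_closed_form(self):
        sigma_corr, _, _ = correct_for_precision(31.62, np.full(10, 10.0))
        assert sigma_corr == pytest.approx(29.998, abs=0.01)

    def test_zero_precision_is_identity(self):
        sigma_corr, fwhm_meas, fwhm_corr = correct_for_precision(
            25.0, np.array([])
        )
        assert sigma_corr == 25.0
        assert fwhm_meas == fwhm_corr

    def test_fwhm_factor(self):
        _, _, fwhm = correct_for_precision(10.0, np.array([]))
        assert fwhm == pytest.approx(23.548, abs=5e-4)

    def test_unresolvable_raises(self):
        with pytest.raises(UnresolvableWidthError):
            correct_for_precision(10.0, np.full(5, 20.0))


class TestMeasureBundleWidth:
    def test_quadrature_and_recovery(self):
        spec = BundleSpec(
            sigma_true_nm=30.0,
            precision_mean_nm=15.0,
            precision_sd_nm=0.0,
            density_per_um=10_000.0,
            seed=11,
        )
        table, truth = simulate_bundle_localizations(spec)
        m = measure_bundle_width(table)
        predicted_meas = FWHM_FACTOR * np.sqrt(30.0**2 + 15.0**2)
        assert m.fwhm_meas_nm == pytest.approx(predicted_meas, rel=0.05)
        assert m.fwhm_corr_nm == pytest.approx(truth.fwhm_true_nm, rel=0.05)
        assert m.linker_nm == 0.0
        assert m.sigma_corr_nm <= m.sigma_meas_nm

    def test_roi_selects_events(self):
        spec = BundleSpec(seed=12)
        table, _ = simulate_bundle_localizations(spec)
        roi = BundleROI(x_min=500, x_max=1500, y_min=-300, y_max=300)
        m = measure_bundle_width(table, roi=roi)
        assert m.n_events_used <= int(roi.contains(table.x_nm, table.y_nm).sum())
        assert m.fwhm_corr_nm == pytest.approx(FWHM_FACTOR * 30.0, rel=0.08)

    def test_min_event_rule(self):
        spec = BundleSpec(seed=13)
        table, _ = simulate_bundle_localizations(spec)
        roi = BundleROI(x_min=0, x_max=10, y_min=-10, y_max=10)
        with pytest.raises(ValueError, match="events"):
            measure_bundle_width(table, roi=roi)

    def test_rotation_invariance_of_width(self):
        spec = BundleSpec(
            sigma_true_nm=30.0, seed=14, centerline_coeffs=(0.0, 0.05, 1e-4)
        )
        table, _ = simulate_bundle_localizations(spec)
        base = measure_bundle_width(table).fwhm_corr_nm
        for ang in (33.0, 120.0):
            th = np.deg2rad(ang)
            rotated = LocalizationTable(
                frame=table.frame,
                x_nm=table.x_nm * np.cos(th) - table.y_nm * np.sin(th),
                y_nm=table.x_nm * np.sin(th) + table.y_nm * np.cos(th),
                precision_nm=table.precision_nm,
            )
            m = measure_bundle_width(rotated)
            assert m.fwhm_corr_nm == pytest.approx(base, rel=0.02)

    def test_correction_small_when_precision_small(self):
        # high-precision events and a wide structure: the deconvolution
        # barely changes the profile
        spec = BundleSpec(
            sigma_true_nm=60.0,
            precision_mean_nm=18.0,
            precision_sd_nm=6.0,
            seed=15,
        )
        table, _ = simulate_bundle_localizations(spec)
        from nanometrics.loc_io import filter_by_precision

        m = measure_bundle_width(filter_by_precision(table, 40.0))
        assert m.sigma_meas_nm >= 60.0
        rel_change = abs(m.fwhm_corr_nm - m.fwhm_meas_nm) / m.fwhm_meas_nm
        assert rel_change < 0.15

    def test_deconvolution_inverts_quadrature_grid(self):
        # spot-check corners of the (sigma_true, sigma_prec) plane
        errs = []
        for st_, sp in [(25, 5), (25, 35), (60, 5), (60, 35), (40, 15)]:
            spec = BundleSpec(
                sigma_true_nm=st_,
                precision_mean_nm=sp,
                precision_sd_nm=0.0,
                density_per_um=3000.0,
                seed=16 + st_ + sp,
            )
            table, truth = simulate_bundle_localizations(spec)
            m = measure_bundle_width(table)
            errs.append(
                abs(m.fwhm_corr_nm - truth.fwhm_true_nm) / truth.fwhm_true_nm
            )
        assert np.median(errs) < 0.10
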