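"""Absolute dose, adaptive SG denoising, gamma analysis, transmission."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import mlcport as m
from mlcport.dosegrid import DoseGrid, GridSpec
from mlcport.qa import (AbsoluteDoseCalibration, GammaCriteria,
                        absolute_dose, calibrate_density, gamma_3d,
                        mean_transmission, output_factor, sg_denoise,
                        simulated_transmission)
from oracles import fixed_window_sg, gamma_brute_force


def make_grid(dose, rel=None, voxel=(0.25, 0.25, 0.25)):
    dose = np.asarray(dose, dtype=float)
    spec = GridSpec((0.0, 0.0, 0.0), voxel, dose.shape)
    if rel is None:
        rel = np.full(dose.shape, 0.02)
    elif np.isscalar(rel):
        rel = np.full(dose.shape, float(rel))
    return DoseGrid(spec, dose, rel)


def gaussian_field(n=24, sigma_vox=8.0, amplitude=100.0):
    ax = np.arange(n) - (n - 1) / 2
    r2 = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
          + ax[None, None, :] ** 2)
    return amplitude * np.exp(-r2 / (2 * sigma_vox**2))


class TestAbsoluteDose:
    CAL = AbsoluteDoseCalibration(D_cal_measured=0.01, D_cal_mc=1e-16)

    def test_zero_stays_zero(self):
        g = make_grid(np.zeros((3, 3, 3)))
        assert absolute_dose(g, self.CAL, 100.0).dose.sum() == 0.0

    def test_direct_substitution(self):
        # raw 2e-16 Gy/particle, Dcal_mc 1e-16, Dcal_meas 0.01, U=100 -> 2 Gy
        g = make_grid(np.full((2, 2, 2), 2e-16))
        out = absolute_dose(g, self.CAL, 100.0)
        np.testing.assert_allclose(out.dose, 2.0)

    def test_u_linearity(self):
        g = make_grid(np.random.default_rng(0).random((4, 4, 4)))
        d1 = absolute_dose(g, self.CAL, 50.0)
        d2 = absolute_dose(g, self.CAL, 100.0)
        np.testing.assert_allclose(2.0 * d1.dose, d2.dose)
        np.testing.assert_array_equal(d1.rel_uncertainty,
                                      g.rel_uncertainty)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            AbsoluteDoseCalibration(0.0, 1e-16)
        with pytest.raises(ValueError, match="backscatter"):
            AbsoluteDoseCalibration(0.01, 1e-16, D_chback=0.1)
        with pytest.raises(ValueError):
            absolute_dose(make_grid(np.ones((2, 2, 2))), self.CAL, 0.0)


class TestSGDenoise:
    def test_noiseless_quadratic_reproduced_exactly(self):
        n = 14
        ax = np.arange(n, dtype=float)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        truth = 50.0 + 2 * x - y + 0.5 * z + 0.3 * x * y - 0.2 * z**2 \
            + 0.1 * x * z
        g = make_grid(truth - truth.min() + 10.0, rel=0.02)
        out = sg_denoise(g)
        np.testing.assert_allclose(out.dose, g.dose, rtol=5e-7)

    def test_two_percent_noise_reduced_below_one_percent(self):
        truth = gaussian_field(n=24)
        rng = np.random.default_rng(1)
        noisy = truth * (1.0 + 0.02 * rng.standard_normal(truth.shape))
        g = make_grid(np.maximum(noisy, 0.0), rel=0.02)
        out = sg_denoise(g)
        high = truth > 0.5 * truth.max()
        rms = np.sqrt(np.mean(((out.dose[high] - truth[high])
                               / truth[high]) ** 2))
        assert rms <= 0.01
        # stated post-filter uncertainties drop as well
        assert np.median(out.rel_uncertainty[high]) < 0.01

    def test_sharp_step_left_unsmoothed(self):
        n = 12
        truth = np.full((n, n, n), 1.0)
        truth[n // 2:] = 0.2
        g = make_grid(truth, rel=1e-4)
        out = sg_denoise(g)
        # adaptive window collapses at the step: values unchanged
        np.testing.assert_allclose(out.dose, truth, atol=1e-9)
        # whereas a fixed-window filter blurs the edge
        blurred = fixed_window_sg(truth, None, hw=2)
        assert np.max(np.abs(blurred - truth)) > 0.05

    def test_flat_region_mean_unbiased(self):
        rng = np.random.default_rng(3)
        truth = np.full((16, 16, 16), 10.0)
        noisy = truth * (1 + 0.02 * rng.standard_normal(truth.shape))
        g = make_grid(noisy, rel=0.02)
        out = sg_denoise(g)
        se = 0.02 * 10.0 / np.sqrt(truth.size)
        assert abs(out.dose.mean() - noisy.mean()) < 5 * se

    def test_commutes_with_absolute_dose(self):
        rng = np.random.default_rng(4)
        truth = gaussian_field(n=12)
        noisy = truth * (1 + 0.02 * rng.standard_normal(truth.shape))
        g = make_grid(np.maximum(noisy, 1e-3), rel=0.02)
        cal = AbsoluteDoseCalibration(0.01, 1e-16)
        a = sg_denoise(absolute_dose(g, cal, 250.0))
        b = absolute_dose(sg_denoise(g), cal, 250.0)
        np.testing.assert_allclose(a.dose, b.dose, rtol=1e-9)

    def test_missing_uncertainties_rejected(self):
        g = make_grid(np.ones((6, 6, 6)), rel=0.0)
        with pytest.raises(ValueError, match="uncertainty"):
            sg_denoise(g)


class TestGamma:
    def test_identical_grids_all_zero(self):
        d = gaussian_field(n=12)
        g = make_grid(d)
        res = gamma_3d(g, g)
        assert res.pass_fraction == 1.0
        assert np.nanmax(res.gamma) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_offset_sits_on_pass_boundary(self):
        # +3% of max in a gradient-free region with 3%/3mm -> gamma = 1.0
        d = np.full((10, 10, 10), 50.0)
        ref = make_grid(d)
        ev = make_grid(d * 1.03)
        res = gamma_3d(ref, ev, GammaCriteria(3.0, 3.0, 20.0))
        np.testing.assert_allclose(res.gamma[res.roi], 1.0, atol=1e-9)
        assert res.pass_fraction == 0.0  # gamma < 1 is strict

    def test_matches_exhaustive_oracle_on_random_grids(self):
        rng = np.random.default_rng(5)
        ref_d = gaussian_filter(rng.random((12, 12, 12)), 1.5)
        ev_d = ref_d * (1 + 0.04 * gaussian_filter(
            rng.standard_normal(ref_d.shape), 2.0))
        ref = make_grid(100 * ref_d / ref_d.max(), voxel=(0.2, 0.2, 0.2))
        ev = make_grid(100 * ev_d / ref_d.max(), voxel=(0.2, 0.2, 0.2))
        crit = GammaCriteria(2.0, 2.0, 20.0)
        res = gamma_3d(ref, ev, crit, subsample_mm=1.0, search_factor=2.0)
        g_o, roi_o, pass_o = gamma_brute_force(ref, ev, crit,
                                               subsample_cm=0.1,
                                               search_radius_cm=0.4)
        np.testing.assert_array_equal(res.roi, roi_o)
        np.testing.assert_allclose(res.gamma[res.roi], g_o[roi_o],
                                   rtol=1e-9, atol=1e-12)
        assert res.pass_fraction == pytest.approx(pass_o)

    def test_asymmetric_under_grid_exchange(self):
        d = gaussian_field(n=10)
        ref = make_grid(d)
        ev = make_grid(0.9 * d)
        r1 = gamma_3d(ref, ev)
        r2 = gamma_3d(ev, ref)
        assert r1.roi.sum() != r2.roi.sum() or not np.allclose(
            np.nan_to_num(r1.gamma), np.nan_to_num(r2.gamma))

    def test_disjoint_grids_rejected(self):
        a = make_grid(np.ones((6, 6, 6)))
        far = GridSpec((100.0, 100.0, 100.0), (0.25,) * 3, (6, 6, 6))
        b = DoseGrid(far, np.ones((6, 6, 6)), np.zeros((6, 6, 6)))
        with pytest.raises(ValueError, match="overlap"):
            gamma_3d(a, b)


class TestTransmissionAnalysis:
    def test_identical_grids_give_unity(self):
        g = make_grid(np.ones((40, 70, 1)), voxel=(0.2, 0.2, 0.2))
        spec = GridSpec((-4.0, -7.0, 0.0), (0.2, 0.2, 0.2), (40, 70, 1))
        g = DoseGrid(spec, np.ones((40, 70, 1)), np.zeros((40, 70, 1)))
        assert mean_transmission(g, g) == pytest.approx(1.0)

    def test_monoenergetic_slab_closed_form(self):
        spec = GridSpec((-2.0, -7.0, 0.0), (0.2, 0.2, 0.2), (20, 70, 1))
        open_d = np.full((20, 70, 1), 5.0)
        t = float(np.exp(-m.default_attenuation().mu("tungsten", 2.0)
                         * 6.9 * 18.9))
        og = DoseGrid(spec, open_d, np.zeros_like(open_d))
        bg = DoseGrid(spec, open_d * t, np.zeros_like(open_d))
        assert mean_transmission(bg, og) == pytest.approx(t, rel=1e-12)

    def test_vanishing_open_dose_rejected(self):
        spec = GridSpec((-2.0, -7.0, 0.0), (0.2, 0.2, 0.2), (20, 70, 1))
        z = np.zeros((20, 70, 1))
        g = DoseGrid(spec, z, z)
        with pytest.raises(ValueError, match="vanishes"):
            mean_transmission(g, g)


class TestDensityCalibration:
    def test_fixed_point_and_round_trip(self, hd120_geom, source_6x):
        kw = dict(n_histories=30_000, seed=13, voxel_cm=0.4, n_batches=2)
        rho_star = 16.0
        g_star = dataclasses.replace(hd120_geom, density=rho_star)
        target = simulated_transmission(g_star, source_6x, **kw)
        rho = calibrate_density(hd120_geom, source_6x, target,
                                tolerance=2e-4, **kw)
        assert rho == pytest.approx(rho_star, rel=0.01)

    def test_unreachable_target_rejected(self, hd120_geom, source_6x):
        with pytest.raises(ValueError, match="must lie"):
            calibrate_density(hd120_geom, source_6x, 0.5)


class TestOutputFactor:
    def test_identity_and_linearity(self):
        d = gaussian_field(n=12)
        spec = GridSpec((-1.5, -1.5, -1.5), (0.25,) * 3, d.shape)
        g = DoseGrid(spec, d, np.zeros_like(d))
        assert output_factor(g, g) == pytest.approx(1.0)
        assert output_factor(g.scaled(0.5), g) == pytest.approx(0.5)
        zero = DoseGrid(spec, np.zeros_like(d), np.zeros_like(d))
        with pytest.raises(ValueError, match="zero"):
            output_factor(g, zero)

    def test_central_kerma_monotone_in_field_size(self, hd120_geom,
                                                  source_6x):
        spec = GridSpec.plane((-1, 1), (-1, 1), 2, 2, 0.0)
        doses = []
        for half in (1.0, 2.5, 5.0):
            ap = m.ApertureState(np.full(60, -half), np.full(60, half),
                                 jaw_x1=-half, jaw_x2=half,
                                 jaw_y1=-half, jaw_y2=half)
            doses.append(m.simulate(ap, source_6x, hd120_geom, spec,
                                    20_000, seed=6, depth_cm=5.0,
                                    n_batches=2))
        of_small = output_factor(doses[0], doses[2], roi_halfwidth_cm=1.0)
        of_mid = output_factor(doses[1], doses[2], roi_halfwidth_cm=1.0)
        assert of_small <= of_mid + 0.02
        assert of_mid <= 1.0 + 0.02
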