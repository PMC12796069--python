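"""Phantom generator: bolus curves, frame averaging, voxelization, determinism."""

import numpy as np
import pytest
from scipy.integrate import quad

from atriaflow.errors import GeometryError, ParameterError
from atriaflow.imaging_io import default_frame_schedule
from atriaflow.kinetics import fine_time_grid, simulate_tissue_tac
from atriaflow.phantom import (
    BolusParams,
    Structure,
    bolus_curve,
    default_phantom_spec,
    frame_average,
    generate_phantom,
    structure_curve,
)


class TestBolusCurve:
    def test_zero_amplitude_is_identically_zero(self):
        t = np.linspace(0, 100, 500)
        assert np.all(bolus_curve(t, 10, 3, 2.5, 0.0) == 0)

    def test_linearity_in_amplitude(self):
        t = np.linspace(0, 100, 500)
        c1 = bolus_curve(t, 10, 3, 2.5, 40.0)
        c2 = bolus_curve(t, 10, 3, 2.5, 80.0)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_zero_before_arrival_and_nonnegative(self):
        t = np.linspace(0, 100, 500)
        c = bolus_curve(t, 30, 3, 2.5, 80.0)
        assert np.all(c[t <= 30] == 0)
        assert np.all(c >= 0)

    def test_invalid_shape_parameters(self):
        with pytest.raises(ParameterError):
            bolus_curve(np.arange(5.0), 0, -1, 2, 1)
        with pytest.raises(ParameterError):
            bolus_curve(np.arange(5.0), 0, 3, 0, 1)

    @pytest.mark.parametrize(
        "t0,alpha,beta", [(5.0, 2.0, 1.5), (10.0, 3.0, 4.0), (20.0, 4.5, 2.0), (0.0, 3.0, 2.5)]
    )
    def test_centroid_matches_quadrature(self, t0, alpha, beta):
        # analytic first moment t0 + beta*(alpha+1) vs numeric quadrature on 0.01 s grid
        t = np.arange(0, 400, 0.01)
        c = bolus_curve(t, t0, alpha, beta, 50.0)
        centroid = np.trapezoid(t * c, t) / np.trapezoid(c, t)
        assert abs(centroid - (t0 + beta * (alpha + 1))) < 0.01


class TestFrameAverage:
    def test_constant_curve(self):
        starts, durs = default_frame_schedule()
        vals = frame_average(lambda t: np.full_like(t, 3.7), starts, durs)
        np.testing.assert_allclose(vals, 3.7, rtol=1e-12)

    def test_linear_curve_hits_frame_midpoints(self):
        starts, durs = default_frame_schedule()
        vals = frame_average(lambda t: 0.5 * t, starts, durs)
        np.testing.assert_allclose(vals, 0.5 * (starts + durs / 2), rtol=1e-9)

    def test_gamma_variate_matches_adaptive_quadrature(self):
        starts, durs = default_frame_schedule()
        bp = BolusParams(t0=12.0, alpha=3.0, beta=2.5, amplitude=80.0, recirc_frac=0.0)
        vals = frame_average(lambda t: bolus_curve(t, bp.t0, bp.alpha, bp.beta, bp.amplitude),
                             starts, durs)
        for i in (2, 3, 4, 8, 12):
            ref, _ = quad(lambda t: bolus_curve(np.array([t]), bp.t0, bp.alpha, bp.beta,
                                                bp.amplitude)[0],
                          starts[i], starts[i] + durs[i], limit=200)
            ref /= durs[i]
            if ref > 1e-9:
                assert abs(vals[i] - ref) / ref < 1e-3


class TestGeneratePhantom:
    def test_ground_truth_volume_matches_analytic_ellipsoid(self, nf_phantom):
        _, truth = nf_phantom
        semi = (27.0, 24.0, 26.0)  # default left atrium semi-axes, mm
        analytic = 4.0 / 3.0 * np.pi * np.prod(semi) / 1000.0
        assert abs(truth.volumes_ml["left_atrium"] - analytic) / analytic < 0.02

    def test_noise_free_output_is_deterministic(self):
        spec = default_phantom_spec(grid_n=32, voxel_mm=6.0, noise_scale=0.0)
        s1, _ = generate_phantom(spec)
        s2, _ = generate_phantom(spec)
        assert np.array_equal(s1.data, s2.data)

    def test_fixed_seed_noise_is_bit_identical(self):
        spec = default_phantom_spec(grid_n=32, voxel_mm=6.0, noise_scale=1.0, seed=42)
        s1, _ = generate_phantom(spec)
        s2, _ = generate_phantom(spec)
        assert np.array_equal(s1.data, s2.data)

    def test_different_seed_changes_noise(self):
        s1, _ = generate_phantom(default_phantom_spec(grid_n=32, voxel_mm=6.0, seed=1))
        s2, _ = generate_phantom(default_phantom_spec(grid_n=32, voxel_mm=6.0, seed=2))
        assert not np.array_equal(s1.data, s2.data)

    def test_structure_masks_are_pairwise_disjoint(self, nf_phantom):
        _, truth = nf_phantom
        names = list(truth.codes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not (truth.mask(a) & truth.mask(b)).any()

    def test_myocardial_tac_matches_forward_model(self):
        # PSF off so a deep myocardial voxel carries the pure tissue curve
        spec = default_phantom_spec(grid_n=48, voxel_mm=4.0, noise_scale=0.0, psf_fwhm_mm=0.0)
        series, truth = generate_phantom(spec)
        tp = truth.tissue["lv_myocardium"]
        t_fine = fine_time_grid(series.total_duration_s, 0.1)
        ca = structure_curve(t_fine, spec.bolus["lv_cavity"])
        crv = structure_curve(t_fine, spec.bolus["rv_cavity"])
        expected = simulate_tissue_tac(tp.mbf, tp.ptf, tp.v_a, tp.v_rv, t_fine, ca, crv,
                                       series.frame_start, series.frame_duration)
        voxel_tacs = series.data[truth.mask("lv_myocardium")]
        observed = voxel_tacs[0]
        np.testing.assert_allclose(observed, expected, rtol=1e-3, atol=1e-4)

    def test_structure_mean_tac_centroid_reproduces_injected_timing(self):
        from atriaflow.firstpass import extract_first_pass_peak

        spec = default_phantom_spec(grid_n=48, voxel_mm=4.0, noise_scale=0.0, psf_fwhm_mm=0.0)
        series, truth = generate_phantom(spec)
        half_min_frame = float(series.frame_duration.min()) / 2.0
        for name in ("svc", "right_atrium", "rv_cavity", "lungs", "left_atrium",
                     "lv_cavity", "aorta"):
            tac = series.data[truth.mask(name)].mean(axis=0)
            peak = extract_first_pass_peak(tac, series.frame_start, series.frame_duration)
            assert peak is not None, name
            assert abs(peak.t_mid - truth.centroid_times_s[name]) <= half_min_frame, name

    def test_voxelized_volume_converges_with_resolution(self):
        # expected voxelization error (averaged over sub-voxel placements of the
        # same ellipsoid) decreases monotonically from 4 to 2 to 1 mm voxels
        semi = np.array([27.0, 24.0, 26.0])
        analytic = 4 / 3 * np.pi * np.prod(semi) / 1000.0
        shifts = [(0, 0, 0), (0.37, 0.71, 0.13), (0.71, 0.13, 0.55),
                  (0.55, 0.89, 0.37), (0.13, 0.55, 0.89), (0.89, 0.37, 0.71)]
        mean_errs = []
        for voxel in (4.0, 2.0, 1.0):
            n = int(round(192 / voxel))
            ax = [np.arange(n) * voxel for _ in range(3)]
            errs = []
            for sh in shifts:
                terms = [(a - (96.0 + sh[i] * voxel)) ** 2 / semi[i] ** 2
                         for i, a in enumerate(ax)]
                inside = (terms[0][:, None, None] + terms[1][None, :, None]
                          + terms[2][None, None, :]) <= 1.0
                errs.append(abs(inside.sum() * voxel**3 / 1000.0 - analytic))
            mean_errs.append(np.mean(errs))
        assert mean_errs[0] >= mean_errs[1] >= mean_errs[2]

    def test_delay_ordering_violation_raises(self):
        spec = default_phantom_spec(grid_n=32, voxel_mm=6.0)
        spec.bolus["lungs"] = BolusParams(25.0, 3.0, 3.0, 17.0)  # after the LA
        with pytest.raises(ParameterError):
            spec.validate()

    def test_structure_outside_grid_raises(self):
        spec = default_phantom_spec(grid_n=32, voxel_mm=6.0)
        spec.structures.append(
            Structure("left_atrium", "ellipsoid", (190.0, 96.0, 96.0),
                      semi_axes=(30.0, 30.0, 30.0))
        )
        with pytest.raises(GeometryError):
            spec.validate()

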