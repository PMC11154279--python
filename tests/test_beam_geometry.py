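import math

import numpy as np
import pytest

from mrtplan import (
    NO_OVERLAP,
    BeamGeometry,
    Collimator,
    FocalSpot,
    collimator_transmittance,
    fluence_pattern,
    fwtm_from_sigma,
    magnification,
    penumbra_overlap_depth,
    sigma_from_fwtm,
    source_profile,
)
from mrtplan.beam_geometry import GeometryError
from mrtplan.microbeam import MicrobeamProfile, profile_metrics


class TestScalarRelations:
    @pytest.mark.parametrize(
        "sigma, expected",
        [(0.58, 2.49), (0.0, 0.0), (1.0, 4.2919)],
    )
    def test_fwtm_from_sigma(self, sigma, expected):
        assert fwtm_from_sigma(sigma) == pytest.approx(expected, abs=5e-3)

    def test_calibrated_sigma_gives_quarter_cm_focal_spot(self):
        # effective focal-spot size at the calibrated source width
        assert round(fwtm_from_sigma(0.58), 1) == 2.5

    def test_fwtm_rejects_negative(self):
        with pytest.raises(GeometryError):
            fwtm_from_sigma(-0.1)

    @pytest.mark.parametrize(
        "sd, delta, expected",
        [(212.0, 6.0, 1.028), (212.0, 0.0, 1.0)],
    )
    def test_magnification(self, sd, delta, expected):
        assert magnification(sd, delta) == pytest.approx(expected, abs=5e-4)

    def test_magnification_projects_ctc_to_430um(self):
        # delta solving 400 um * M = 430 um
        delta = 212.0 * (430.0 / 400.0 - 1.0)
        assert delta == pytest.approx(15.9, abs=0.1)
        assert 400.0 * magnification(212.0, delta) == pytest.approx(430.0)

    def test_magnification_rejects_bad_sd(self):
        with pytest.raises(GeometryError):
            magnification(0.0, 5.0)


class TestSourceProfile:
    def test_mode_and_ratio(self):
        fs = FocalSpot(0.58)
        f0 = source_profile(0.0, fs)
        assert f0 == pytest.approx(1.0 / (0.58 * math.sqrt(2 * math.pi)))
        assert source_profile(0.58, fs) / f0 == pytest.approx(
            math.exp(-0.5), rel=1e-12
        )

    def test_normalization(self):
        fs = FocalSpot(0.58)
        x = np.linspace(-6, 6, 20001)
        integral = np.trapezoid(source_profile(x, fs), x)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_point_source_signals_other_path(self):
        with pytest.raises(GeometryError):
            source_profile(0.0, FocalSpot(0.0))


class TestCollimatorTransmittance:
    def test_slit_center_septum_and_aperture(self, geometry, e_eff):
        coll = geometry.collimator
        assert collimator_transmittance(0.0, coll, 20.0, e_eff) == 1.0
        septum = collimator_transmittance(0.2, coll, 20.0, e_eff)
        assert 0 < septum < 1e-3  # 7 mm tungsten leaks essentially nothing
        assert collimator_transmittance(10.5, coll, 20.0, e_eff) == 0.0

    def test_periodicity_inside_field(self, geometry, e_eff):
        # offset keeps samples off the exact slit edges, where binary float
        # rounding of the modulo could differ between x and x + ctc
        x = np.linspace(-4.0, 4.0, 1601) + 1.7e-4
        coll = geometry.collimator
        t1 = collimator_transmittance(x, coll, 20.0, e_eff)
        t2 = collimator_transmittance(x + 0.4, coll, 20.0, e_eff)
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_energy_outside_table_raises(self, geometry):
        from mrtplan.materials import EnergyRangeError

        with pytest.raises(EnergyRangeError):
            collimator_transmittance(0.2, geometry.collimator, 20.0, 500.0)


class TestFluencePattern:
    def test_two_code_paths_agree(self, geometry, e_eff):
        # 5-slit toy window around the axis
        x = np.arange(-1000, 1001) * 1e-3
        for y in (216.5, 218.0, 250.0):
            conv = fluence_pattern(x, y, geometry, energy_kev=e_eff)
            quad = fluence_pattern(
                x, y, geometry, energy_kev=e_eff, method="quadrature"
            )
            assert np.max(np.abs(conv - quad)) / conv.max() < 1e-3

    def test_point_source_is_magnified_transmittance(self, geometry, e_eff, um_grid):
        g0 = geometry.with_sigma(0.0)
        y = 250.0
        theta = fluence_pattern(um_grid, y, g0, energy_kev=e_eff, normalize=False)
        direct = collimator_transmittance(
            um_grid * g0.sd_mm / y,
            g0.collimator,
            g0.field_mm[0],
            e_eff,
            averaging_width_mm=(um_grid[1] - um_grid[0]) * g0.sd_mm / y,
        )
        np.testing.assert_allclose(theta, direct, atol=1e-12)

    def test_period_mean_normalization(self, geometry, e_eff, um_grid):
        theta = fluence_pattern(um_grid, 230.0, geometry, energy_kev=e_eff)
        period = geometry.projected_ctc_um(230.0) / 1000.0
        n_per = int((um_grid[-1] - um_grid[0]) / period)
        half = 0.5 * n_per * period
        mask = (um_grid >= -half) & (um_grid <= half)
        assert theta[mask].mean() == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_about_slit_centers(self, geometry, e_eff, um_grid):
        theta = fluence_pattern(um_grid, 230.0, geometry, energy_kev=e_eff)
        assert np.max(np.abs(theta - theta[::-1])) / theta.max() < 1e-9

    def test_projected_ctc_regression(self, geometry, e_eff):
        # peak positions on the pattern track ctc x magnification exactly
        x = np.arange(-1500, 1501) * 1e-3
        for y in (218.0, 240.0):
            theta = fluence_pattern(x, y, geometry, energy_kev=e_eff)
            prof = MicrobeamProfile(x * 1000.0, theta, y)
            m = profile_metrics(
                prof, expected_period_um=geometry.projected_ctc_um(y)
            )
            expected = geometry.collimator.ctc_um * y / geometry.sd_mm
            assert m.ctc_measured_um == pytest.approx(expected, rel=3e-3)

    def test_duty_cycle_pinhole_limit(self, e_eff):
        # zero-sigma, zero-leakage: fraction above half max = slit/ctc at any y
        g = BeamGeometry(
            focal_spot=FocalSpot(0.0),
            collimator=Collimator(leakage=0.0),
        )
        x = np.arange(-1000, 1001) * 1e-3
        for y in (212.0, 250.0, 300.0):
            theta = fluence_pattern(x, y, g, normalize=False)
            period = g.projected_ctc_um(y) / 1000.0
            n_per = int((x[-1] - x[0]) / period)
            half_w = 0.5 * n_per * period
            mask = (x >= -half_w) & (x <= half_w)
            duty = (theta[mask] > 0.5 * theta.max()).mean()
            assert duty == pytest.approx(30.0 / 400.0, rel=0.05)

    def test_collimator_plane_limit(self, geometry, e_eff, um_grid):
        theta = fluence_pattern(
            um_grid, geometry.sd_mm, geometry, energy_kev=e_eff, normalize=False
        )
        direct = collimator_transmittance(
            um_grid,
            geometry.collimator,
            geometry.field_mm[0],
            e_eff,
            averaging_width_mm=um_grid[1] - um_grid[0],
        )
        np.testing.assert_allclose(theta, direct, atol=1e-12)


class TestPenumbraOverlap:
    def test_closed_form(self):
        g = BeamGeometry(focal_spot=FocalSpot(sigma_from_fwtm(2.5)))
        # d*sd/(d - ctc + slit) - sd with d=2.5, ctc=0.4, slit=0.03, sd=212
        assert penumbra_overlap_depth(g) == pytest.approx(36.83, abs=0.05)

    def test_parallel_edge_limit(self):
        g = BeamGeometry(focal_spot=FocalSpot(0.0))
        assert penumbra_overlap_depth(g) == NO_OVERLAP

    def test_monotone_in_focal_spot_size(self):
        depths = [
            penumbra_overlap_depth(
                BeamGeometry(focal_spot=FocalSpot(sigma_from_fwtm(d)))
            )
            for d in (2.0, 2.5, 3.0)
        ]
        assert depths[0] > depths[1] > depths[2]
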