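import numpy as np
import pytest

from mrtplan import (
    BeamGeometry,
    Collimator,
    FocalSpot,
    Kernel1D,
    MicrobeamProfile,
    collimator_transmittance,
    electron_kernel,
    profile_metrics,
    reconstruct_profile,
    source_profile,
)
from mrtplan.microbeam import ProfileError


class TestElectronKernel:
    def test_unit_integral(self, spectrum):
        k = electron_kernel(spectrum, 1.19)
        assert k.weights.sum() * k.pitch_um == pytest.approx(1.0, rel=1e-9)

    def test_width_scales_inversely_with_density(self, spectrum):
        k1 = electron_kernel(spectrum, 1.0, pitch_um=0.1)
        k2 = electron_kernel(spectrum, 2.0, pitch_um=0.1)
        assert k2.fwhm_um() == pytest.approx(k1.fwhm_um() / 2.0, rel=0.01)

    def test_constant_profile_invariant_under_convolution(self, spectrum):
        k = electron_kernel(spectrum, 1.19)
        const = np.ones(5000)
        out = np.convolve(const, k.weights, mode="same") * k.pitch_um
        inner = out[len(k.weights) : -len(k.weights)]
        np.testing.assert_allclose(inner, 1.0, rtol=1e-9)

    def test_non_normalizable_kernel_rejected(self):
        with pytest.raises(ValueError):
            Kernel1D(np.array([-1.0, 0.0, 1.0]), np.zeros(3))

    def test_symmetric(self, spectrum):
        k = electron_kernel(spectrum, 1.19)
        np.testing.assert_allclose(k.weights, k.weights[::-1])


class TestReconstruction:
    def delta_kernel(self):
        return Kernel1D(np.array([-1.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0]))

    def test_delta_kernel_point_source_degenerate_limit(self, e_eff):
        g = BeamGeometry(focal_spot=FocalSpot(0.0))
        y = 250.0
        prof = reconstruct_profile(
            2.0, 0.5, g, self.delta_kernel(), y, energy_kev=e_eff
        )
        # magnified transmittance scaled by primary + flat scatter pedestal;
        # the unit-period-mean rectangle has height ctc/slit at zero leakage
        m = profile_metrics(prof, expected_period_um=g.projected_ctc_um(y))
        # normalized rectangle height = ctc/slit (unit period mean)
        assert m.peak_dose == pytest.approx(2.0 * 400.0 / 30.0 + 0.5, rel=2e-2)
        assert m.valley_dose == pytest.approx(0.5, rel=1e-6)

    def test_wide_kernel_flattens_to_total_dose(self, geometry, e_eff):
        # kernel much wider than the period: PVDR -> 1, dose -> dp + ds
        x = np.arange(-3000, 3001) * 1.0
        w = np.exp(-0.5 * (x / 800.0) ** 2)
        kern = Kernel1D(x, w / (w.sum() * 1.0))
        prof = reconstruct_profile(1.5, 0.5, geometry, kern, 230.0, energy_kev=e_eff)
        inner = np.abs(prof.positions_um) < 500
        np.testing.assert_allclose(prof.dose[inner], 2.0, rtol=0.02)

    def test_against_direct_quadrature_oracle(self, geometry, e_eff, kernel_pmma):
        # brute-force double integral of source x transmittance, then kernel
        # smearing by direct summation (no FFT/convolve shortcuts)
        y = 230.0
        dp, ds = 1.3, 0.21
        prof = reconstruct_profile(
            dp, ds, geometry, kernel_pmma, y, x_span_mm=2.0, energy_kev=e_eff
        )
        x_mm = prof.positions_um / 1000.0
        sd = geometry.sd_mm
        xp = np.linspace(-6 * 0.58, 6 * 0.58, 2001)
        fs = source_profile(xp, geometry.focal_spot)
        kx = kernel_pmma.offsets_um / 1000.0
        kw = kernel_pmma.weights

        # theta on a padded grid by direct quadrature
        pad = (kx[-1] - kx[0]) / 2 + 1.0
        pitch = x_mm[1] - x_mm[0]
        xg = np.arange(x_mm[0] - pad, x_mm[-1] + pad + pitch / 2, pitch)
        scale = 1.0 - sd / y
        xcm = xp[None, :] * scale + xg[:, None] * (sd / y)
        fc = collimator_transmittance(
            xcm.ravel(),
            geometry.collimator,
            geometry.field_mm[0],
            e_eff,
            averaging_width_mm=abs(scale) * (xp[1] - xp[0]),
        ).reshape(xcm.shape)
        theta = np.trapezoid(fc * fs[None, :], xp, axis=1)
        period = geometry.projected_ctc_um(y) / 1000.0
        n_per = max(int((xg[-1] - xg[0]) / period), 1)
        half = 0.5 * n_per * period
        theta = theta / theta[(xg >= -half) & (xg <= half)].mean()

        # kernel smearing by direct summation at each requested position
        oracle = np.empty_like(x_mm)
        for i, xi in enumerate(x_mm):
            # kernel weights are per um; spacing kx is in mm
            oracle[i] = np.sum(
                np.interp(xi - kx, xg, theta) * kw
            ) * (kx[1] - kx[0]) * 1000.0
        oracle = dp * oracle + ds
        assert np.max(np.abs(prof.dose - oracle)) / oracle.max() < 0.005

    def test_convolution_order_commutes(self, geometry, e_eff, kernel_pmma):
        # smearing theta with the kernel equals smearing the transmittance
        # first and blurring with the source after (convolution commutes)
        y = 230.0
        pitch_mm = 1e-3
        n = 2500
        x = np.arange(-n, n + 1) * pitch_mm
        sd = geometry.sd_mm
        fc = collimator_transmittance(
            x * sd / y,
            geometry.collimator,
            geometry.field_mm[0],
            e_eff,
            averaging_width_mm=pitch_mm * sd / y,
        )
        sigma_proj = 0.58 * (y - sd) / sd
        ks = np.arange(-6 * sigma_proj, 6 * sigma_proj, pitch_mm)
        fs = np.exp(-0.5 * (ks / sigma_proj) ** 2)
        fs /= fs.sum()
        kel = np.interp(x * 1000.0, kernel_pmma.offsets_um, kernel_pmma.weights)
        kel = kel[np.abs(x * 1000.0) <= kernel_pmma.offsets_um[-1]]
        kel = kel / kel.sum()

        a = np.convolve(np.convolve(fc, fs, "same"), kel, "same")
        b = np.convolve(np.convolve(fc, kel, "same"), fs, "same")
        inner = slice(600, -600)
        np.testing.assert_allclose(a[inner], b[inner], rtol=1e-8, atol=1e-12)

    def test_too_coarse_grid_rejected(self, geometry, kernel_pmma):
        with pytest.raises(ProfileError):
            reconstruct_profile(
                1.0, 0.0, geometry, kernel_pmma, 230.0, pitch_um=10.0
            )

    def test_period_mean_conservation(self, geometry, e_eff, kernel_pmma):
        for y, dp, ds in [(220.0, 1.0, 0.2), (250.0, 0.4, 0.3)]:
            prof = reconstruct_profile(
                dp, ds, geometry, kernel_pmma, y, x_span_mm=4.0, energy_kev=e_eff
            )
            mean = prof.period_mean(geometry.projected_ctc_um(y))
            assert mean == pytest.approx(dp + ds, rel=1e-3)

    def test_fwhm_and_ctc_nondecreasing_with_depth(self, geometry, e_eff, kernel_pmma):
        fwhms, ctcs = [], []
        for y in (220.0, 235.0, 250.0):
            prof = reconstruct_profile(
                1.0, 0.1, geometry, kernel_pmma, y, energy_kev=e_eff
            )
            m = profile_metrics(prof, expected_period_um=geometry.projected_ctc_um(y))
            fwhms.append(m.fwhm_um)
            ctcs.append(m.ctc_measured_um)
        assert fwhms == sorted(fwhms)
        assert ctcs == sorted(ctcs)

    def test_pvdr_decreases_with_scatter(self, geometry, e_eff, kernel_pmma):
        pvdrs = []
        for ds in (0.05, 0.2, 0.5):
            prof = reconstruct_profile(
                1.0, ds, geometry, kernel_pmma, 230.0, energy_kev=e_eff
            )
            m = profile_metrics(prof, expected_period_um=geometry.projected_ctc_um(230.0))
            pvdrs.append(m.pvdr)
        assert pvdrs[0] > pvdrs[1] > pvdrs[2]


class TestMetrics:
    def rectangular_profile(self, w=100.0, p=400.0, high=10.0, low=1.0, n_per=7):
        x = np.arange(-n_per * p / 2, n_per * p / 2 + 0.5, 1.0)
        d = np.full_like(x, low)
        for k in range(-(n_per // 2), n_per // 2 + 1):
            d[np.abs(x - k * p) <= w / 2] = high
        return MicrobeamProfile(x, d, 230.0)

    def test_ideal_rectangular_array(self):
        prof = self.rectangular_profile()
        m = profile_metrics(prof, expected_period_um=400.0)
        assert m.peak_dose == pytest.approx(10.0)
        assert m.valley_dose == pytest.approx(1.0)
        assert m.pvdr == pytest.approx(10.0)
        assert m.fwhm_um == pytest.approx(100.0, abs=2.0)
        assert m.ctc_measured_um == pytest.approx(400.0, abs=1.0)

    def test_pvdr_is_exact_ratio(self):
        m = profile_metrics(self.rectangular_profile(), expected_period_um=400.0)
        assert m.pvdr == m.peak_dose / m.valley_dose

    def test_ctc_at_6mm_beyond_collimator(self, geometry, e_eff, kernel_pmma):
        # the measured period 6 mm past the collimator is 1.028x the
        # collimator period (divergence magnification)
        y = geometry.sd_mm + 6.0
        prof = reconstruct_profile(
            1.0, 0.05, geometry, kernel_pmma, y, energy_kev=e_eff
        )
        m = profile_metrics(prof, expected_period_um=geometry.projected_ctc_um(y))
        assert m.ctc_measured_um / 400.0 == pytest.approx(1.028, abs=0.003)

    def test_flat_profile_rejected(self):
        prof = MicrobeamProfile(np.arange(100.0), np.ones(100), 230.0)
        with pytest.raises(ProfileError):
            profile_metrics(prof)
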