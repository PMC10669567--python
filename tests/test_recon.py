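"""Reconstruction chain: DC removal, k-linearization, dispersion, PSF metrics."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from octdent import (
    SpectralFrame,
    SystemSpec,
    axial_resolution,
    compensate_dispersion,
    in_tissue,
    psf_fwhm,
    reconstruct,
    remove_dc,
    resample_to_k,
    usaf_bar_width,
)
from octdent.phantom import synthesize_interferogram


def _fringe_frame(spec, z_um=200.0, **kw):
    return synthesize_interferogram([z_um], spec, **kw)


class TestRemoveDc:
    def test_reference_only_frame_becomes_zero(self, spec):
        lam = spec.wavelength_axis_nm
        ref = np.exp(-(((lam - 775.0) / 60.0) ** 2))
        frame = SpectralFrame(np.tile(ref, (3, 1)), lam, reference=ref)
        out = remove_dc(frame)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-15)

    def test_fringe_preserved_offset_removed(self, spec):
        lam = spec.wavelength_axis_nm
        ref = 1.0 + 0.5 * np.exp(-(((lam - 775.0) / 60.0) ** 2))
        fringe = 0.3 * np.cos(0.15 * np.arange(len(lam)))
        frame = SpectralFrame((ref + fringe)[None, :], lam, reference=ref)
        out = remove_dc(frame)
        np.testing.assert_allclose(out.data[0], fringe, atol=1e-9 * np.abs(frame.data).max())

    def test_mismatched_reference_rejected(self, spec):
        lam = spec.wavelength_axis_nm
        with pytest.raises(ValueError, match="reference"):
            SpectralFrame(np.zeros((2, len(lam))), lam, reference=np.zeros(10))

    def test_without_reference_subtracts_mean_line(self, spec):
        lam = spec.wavelength_axis_nm
        rng = np.random.default_rng(0)
        data = 5.0 + rng.normal(size=(8, len(lam)))
        out = remove_dc(SpectralFrame(data, lam))
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)


class TestResampleToK:
    def test_constant_spectrum_unchanged(self, spec):
        lam = spec.wavelength_axis_nm
        out = resample_to_k(SpectralFrame(np.full((1, len(lam)), 2.5), lam))
        np.testing.assert_allclose(out.data, 2.5, rtol=1e-9)

    def test_round_trip_of_smooth_spectrum(self, spec):
        """lambda -> k -> lambda spline round trip reproduces the input."""
        lam = spec.wavelength_axis_nm
        smooth = np.exp(-(((lam - 775.0) / 60.0) ** 2)) * (1 + 0.1 * np.sin(lam / 40.0))
        kframe = resample_to_k(SpectralFrame(smooth[None, :], lam))
        back = CubicSpline(kframe.k_inv_nm, kframe.data[0])(2 * np.pi / lam)
        assert np.max(np.abs(back - smooth)) < 1e-6 * np.abs(smooth).max()

    def test_k_linearization_sharpens_fringe_peak(self, spec):
        """A cos(2 k z) fringe sampled in lambda is chirped; resampling
        restores a single FFT frequency and shrinks the peak FWHM."""
        frame = remove_dc(_fringe_frame(spec, 400.0))
        raw_int = np.abs(np.fft.fft(frame.data[0], 4 * frame.data.shape[1])) ** 2
        res_int = np.abs(
            np.fft.fft(resample_to_k(frame).data[0], 4 * frame.data.shape[1])
        ) ** 2
        n = len(raw_int) // 2
        w_raw = psf_fwhm(raw_int[:n], 1.0)
        w_res = psf_fwhm(res_int[:n], 1.0)
        assert w_res < w_raw

    def test_non_monotonic_axis_rejected(self):
        lam = np.array([675.0, 700.0, 690.0, 875.0])
        with pytest.raises(ValueError, match="monotonic"):
            SpectralFrame(np.zeros((1, 4)), lam)


class TestDispersionCompensation:
    def test_zero_coefficients_identity(self, spec):
        kframe = resample_to_k(remove_dc(_fringe_frame(spec)))
        out = compensate_dispersion(kframe, (0.0, 0.0))
        np.testing.assert_allclose(out.data, kframe.data, atol=1e-12)

    def test_known_coefficients_restore_psf(self, spec):
        """Compensating with the synthesis coefficients recovers the
        dispersion-free width within 5%."""
        clean = axial_resolution(_fringe_frame(spec), spec)
        blurred = _fringe_frame(spec, dispersion=(2e7, 1e10))
        fixed = axial_resolution(blurred, spec, dispersion=(2e7, 1e10))
        assert fixed == pytest.approx(clean, rel=0.05)

    def test_auto_search_restores_psf(self, spec):
        clean = axial_resolution(_fringe_frame(spec), spec)
        blurred = _fringe_frame(spec, dispersion=(1.5e7, 0.0))
        fixed = axial_resolution(blurred, spec, dispersion="auto")
        assert fixed == pytest.approx(clean, rel=0.10)

    def test_psf_broadening_monotone_in_a2(self, spec):
        widths = [
            axial_resolution(_fringe_frame(spec, dispersion=(a2, 0.0)), spec)
            for a2 in (0.0, 1e7, 2e7, 4e7)
        ]
        assert all(w1 <= w2 + 1e-9 for w1, w2 in zip(widths, widths[1:]))


class TestReconstruct:
    def test_peak_at_reflector_depth(self, spec):
        for depth in (150.0, 400.0, 700.0):
            vol = reconstruct(_fringe_frame(spec, depth), spec, window="hann")
            peak_um = np.argmax(vol.data[0, 0]) * vol.axial_spacing_um
            assert abs(peak_um - depth) <= vol.axial_spacing_um

    def test_empty_frame_gives_zero_bscan(self, spec):
        lam = spec.wavelength_axis_nm
        vol = reconstruct(SpectralFrame(np.zeros((2, len(lam))), lam), spec)
        assert np.all(vol.data == 0.0)

    def test_axial_resolution_matches_instrument(self, spec):
        """The 675-875 nm spectrometer span yields ~2.6 um in air (the
        instrument's quoted value, to its printed precision)."""
        fwhm = axial_resolution(_fringe_frame(spec), spec)
        assert round(fwhm, 1) <= 2.6

    def test_axial_resolution_matches_coherence_length(self):
        """With the Gaussian source fully sampled (negligible spectral
        truncation) the modulus-PSF FWHM equals (2 ln2/pi) lambda0^2/dlambda."""
        wide = SystemSpec(spectral_span_nm=(575.0, 975.0))
        fwhm = axial_resolution(_fringe_frame(wide), wide)
        assert fwhm == pytest.approx(wide.coherence_length_air_um, rel=0.02)

    def test_energy_conserved_spectrum_to_ascan(self, spec):
        """Parseval: windowed spectral power equals total A-scan power."""
        kframe = resample_to_k(remove_dc(_fringe_frame(spec, 300.0)))
        win = np.hanning(kframe.data.shape[1])
        x = kframe.data[0] * win
        intensity = np.abs(np.fft.fft(x)) ** 2
        assert intensity.sum() == pytest.approx(len(x) * np.sum(x**2), rel=1e-6)

    def test_intensity_scales_quadratically(self, spec):
        frame = _fringe_frame(spec, 250.0)
        v1 = reconstruct(frame, spec, window="none")
        scaled = SpectralFrame(
            frame.data * 3.0, frame.wavelength_nm,
            reference=frame.reference * 3.0,
        )
        v3 = reconstruct(scaled, spec, window="none")
        np.testing.assert_allclose(v3.data, 9.0 * v1.data, rtol=1e-5)


class TestPsfMetrics:
    def test_gaussian_profile_fwhm_identity(self):
        x = np.arange(200, dtype=float)
        profile = np.exp(-0.5 * ((x - 100.0) / 2.0) ** 2)
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * 2.0
        # linear interpolation on 1-px sampling is good to ~1%
        assert psf_fwhm(profile, 1.0) == pytest.approx(expected, rel=0.02)

    def test_delta_flagged_under_resolved(self):
        profile = np.zeros(64)
        profile[20] = 1.0
        with pytest.warns(UserWarning, match="under-resolved"):
            width = psf_fwhm(profile, 1.0)
        assert width <= 2.0

    def test_flat_profile_has_no_peak(self):
        with pytest.raises(ValueError, match="peak"):
            psf_fwhm(np.ones(64), 1.0)

    @pytest.mark.parametrize(
        "length_air, n, expected",
        [(2.6, 1.6, 1.63), (7.0, 1.0, 7.0), (0.0, 1.6, 0.0)],
    )
    def test_in_tissue_conversion(self, length_air, n, expected):
        # report with round-half-up, the convention of the printed values
        value = in_tissue(length_air, n)
        assert np.floor(value * 100 + 0.5) / 100 == expected

    def test_in_tissue_rejects_subunity_index(self):
        with pytest.raises(ValueError):
            in_tissue(2.6, 0.9)

    @pytest.mark.parametrize(
        "group, element, expected",
        [(8, 1, 1.95), (8, 2, 1.74), (0, 1, 500.0)],
    )
    def test_usaf_bar_width(self, group, element, expected):
        assert round(usaf_bar_width(group, element), 2) == expected

    def test_usaf_element_out_of_range(self):
        with pytest.raises(ValueError):
            usaf_bar_width(8, 7)
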