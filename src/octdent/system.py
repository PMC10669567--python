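"""Optical and acquisition parameters of the spectral-domain OCT system.

The defaults describe an ultrahigh-resolution SD-OCT instrument: a broadband
source centered at 775 nm with a 105 nm spectral FWHM, a 2048-pixel
spectrometer covering 675-875 nm, and a high-NA objective whose confocal
gating is summarized by a focal depth and a Rayleigh length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SystemSpec:
    """Optical/acquisition parameters shared by synthesis and reconstruction.

    Parameters
    ----------
    center_wavelength_nm : float
        Source center wavelength lambda_0.
    spectral_fwhm_nm : float
        FWHM of the (Gaussian) source power spectrum, Delta-lambda.
    spectral_span_nm : tuple of float
        Wavelength range seen by the spectrometer (min, max).
    n_spectral_samples : int
        Number of camera pixels, sampled uniformly in wavelength.
    lateral_spacing_um : float
        Lateral pixel pitch of a B-scan.
    n_enamel, n_calculus : float
        Group refractive indices used to convert optical path length to
        geometric depth inside enamel and calculus.
    focal_depth_um : float
        Depth of the beam focus below the tissue surface (tissue scale).
    rayleigh_um : float
        Rayleigh length of the focused beam; the confocal collection factor
        is 1 / (1 + ((z - z_f)/z_R)^2).
    """

    center_wavelength_nm: float = 775.0
    spectral_fwhm_nm: float = 105.0
    spectral_span_nm: tuple[float, float] = (675.0, 875.0)
    n_spectral_samples: int = 2048
    lateral_spacing_um: float = 1.0
    n_enamel: float = 1.6
    n_calculus: float = 1.6
    focal_depth_um: float = 0.0
    rayleigh_um: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.spectral_span_nm
        if not lo < self.center_wavelength_nm < hi:
            raise ValueError(
                f"center wavelength {self.center_wavelength_nm} nm outside "
                f"spectral span {self.spectral_span_nm}"
            )
        if not self.spectral_fwhm_nm < hi - lo:
            raise ValueError("spectral FWHM must be smaller than the span width")
        if self.n_enamel < 1.0:
            raise ValueError("refractive index of enamel must be >= 1")
        if self.rayleigh_um <= 0:
            raise ValueError("Rayleigh length must be positive")

    @property
    def wavelength_axis_nm(self) -> np.ndarray:
        """Uniform-in-wavelength camera axis (nm), ascending."""
        lo, hi = self.spectral_span_nm
        return np.linspace(lo, hi, self.n_spectral_samples)

    @property
    def k0_inv_nm(self) -> float:
        """Center wavenumber k0 = 2*pi/lambda_0 in rad/nm."""
        return TWO_PI / self.center_wavelength_nm

    @property
    def k_span_inv_nm(self) -> float:
        """Total wavenumber span covered by the spectrometer (rad/nm)."""
        lo, hi = self.spectral_span_nm
        return TWO_PI / lo - TWO_PI / hi

    @property
    def axial_spacing_air_um(self) -> float:
        """Depth pixel pitch in air of an FFT-reconstructed A-scan (um).

        For a signal cos(2 k z) sampled on N uniform wavenumber points with
        pitch dk, DFT bin m maps to z = m * pi / (N dk).
        """
        n = self.n_spectral_samples
        dk = self.k_span_inv_nm / (n - 1)
        return float(np.pi / (n * dk) * 1e-3)

    @property
    def coherence_length_air_um(self) -> float:
        """Closed-form axial resolution (2 ln2 / pi) lambda_0^2 / Dlambda, in air."""
        lam0 = self.center_wavelength_nm
        return float((2.0 * np.log(2.0) / np.pi) * lam0**2 / self.spectral_fwhm_nm * 1e-3)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spectral_span_nm"] = list(self.spectral_span_nm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SystemSpec":
        d = dict(d)
        d["spectral_span_nm"] = tuple(d["spectral_span_nm"])
        return cls(**d)
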