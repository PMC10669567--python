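"""Spectral-domain OCT reconstruction and resolution characterization.

The chain inverts what the spectrometer records: per A-line, subtract the
reference (DC) spectrum, resample the uniform-in-wavelength samples onto a
uniform wavenumber grid (the camera samples uniformly in lambda, the FFT
needs uniform k), apodize, cancel residual dispersion with a polynomial
phase in k, and Fourier transform to the axial point-spread function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .system import SystemSpec, TWO_PI
from .volume import OctVolume

__all__ = [
    "SpectralFrame",
    "KFrame",
    "remove_dc",
    "resample_to_k",
    "compensate_dispersion",
    "reconstruct",
    "psf_fwhm",
    "axial_resolution",
    "in_tissue",
    "usaf_bar_width",
]

WINDOWS = ("hann", "gaussian", "none")


@dataclass
class SpectralFrame:
    """Raw camera frame: (A-lines x spectral samples) on a wavelength axis."""

    data: np.ndarray
    wavelength_nm: np.ndarray
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        if self.wavelength_nm.ndim != 1 or len(self.wavelength_nm) != self.data.shape[1]:
            raise ValueError("wavelength axis length must match the spectral sample count")
        d = np.diff(self.wavelength_nm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength axis must be strictly monotonic")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != (self.data.shape[1],):
                raise ValueError(
                    f"reference spectrum length {self.reference.shape} does not "
                    f"match {self.data.shape[1]} spectral samples"
                )


@dataclass
class KFrame:
    """DC-removed fringes resampled onto a uniform wavenumber grid (rad/nm)."""

    data: np.ndarray
    k_inv_nm: np.ndarray

    @property
    def dk(self) -> float:
        return float(self.k_inv_nm[1] - self.k_inv_nm[0])

    @property
    def k_center(self) -> float:
        return float(0.5 * (self.k_inv_nm[0] + self.k_inv_nm[-1]))

    def axial_spacing_air_um(self, pad: int = 1) -> float:
        """Depth pitch in air of the FFT of this grid, zero-padded ``pad`` x."""
        n = len(self.k_inv_nm) * pad
        return float(np.pi / (n * self.dk) * 1e-3)


def remove_dc(frame: SpectralFrame) -> SpectralFrame:
    """Subtract the non-interferometric (DC) spectrum from every A-line.

    Uses the recorded reference-arm spectrum when available, otherwise the
    mean spectrum across A-lines.
    """
    if frame.reference is not None:
        out = frame.data - frame.reference[None, :]
    else:
        out = frame.data - frame.data.mean(axis=0, keepdims=True)
    return SpectralFrame(data=out, wavelength_nm=frame.wavelength_nm, reference=None)


def resample_to_k(frame: SpectralFrame) -> KFrame:
    """Cubic-spline interpolation from uniform wavelength to uniform k = 2 pi / lambda.

    The output grid has the same number of samples and spans exactly the same
    wavenumber interval, so the endpoints are preserved.
    """
    lam = frame.wavelength_nm
    k = TWO_PI / lam
    order = np.argsort(k)
    k_sorted = k[order]
    k_uniform = np.linspace(k_sorted[0], k_sorted[-1], len(k))
    spline = CubicSpline(k_sorted, frame.data[:, order], axis=1)
    return KFrame(data=spline(k_uniform), k_inv_nm=k_uniform)


def _dispersion_phase(k: np.ndarray, k0: float, a2: float, a3: float) -> np.ndarray:
    dk = k - k0
    return a2 * dk**2 + a3 * dk**3


def compensate_dispersion(
    kframe: KFrame,
    coeffs: tuple[float, float] | str = (0.0, 0.0),
    k0: float | None = None,
    search_a2: float = 5e7,
    search_a3: float = 5e10,
) -> KFrame:
    """Cancel polynomial dispersion by a phase-only multiply in k.

    The analytic signal (Hilbert transform along k) is multiplied by
    exp(-i (a2 (k-k0)^2 + a3 (k-k0)^3)) and the real part retained, i.e. the
    compensation phase is the negative of the synthesis phase: passing the
    coefficients a frame was synthesized with undoes them.  ``coeffs="auto"``
    grid-searches (a2, a3) in [-search_a2, +search_a2] x [-search_a3,
    +search_a3] maximizing the image sharpness sum(I^1.3), coarse-to-fine.
    """
    if k0 is None:
        k0 = kframe.k_center

    if isinstance(coeffs, str):
        if coeffs != "auto":
            raise ValueError("coeffs must be a (a2, a3) pair or 'auto'")
        coeffs = _auto_dispersion(kframe, k0, search_a2, search_a3)

    a2, a3 = coeffs
    if a2 == 0.0 and a3 == 0.0:
        return KFrame(data=kframe.data.copy(), k_inv_nm=kframe.k_inv_nm)
    analytic = hilbert(kframe.data, axis=1)
    phase = _dispersion_phase(kframe.k_inv_nm, k0, a2, a3)
    out = np.real(analytic * np.exp(-1j * phase)[None, :])
    return KFrame(data=out, k_inv_nm=kframe.k_inv_nm)


def _sharpness(kframe: KFrame, k0: float, a2: float, a3: float) -> float:
    analytic = hilbert(kframe.data, axis=1)
    phase = _dispersion_phase(kframe.k_inv_nm, k0, a2, a3)
    spec = np.real(analytic * np.exp(-1j * phase)[None, :])
    intensity = np.abs(np.fft.rfft(spec, axis=1)) ** 2
    return float(np.sum(intensity**1.3))


def _auto_dispersion(kframe: KFrame, k0: float, r2: float, r3: float) -> tuple[float, float]:
    """Coarse-to-fine grid search of the sharpness metric; deterministic."""
    best = (0.0, 0.0)
    c2, c3 = 0.0, 0.0
    for _level in range(3):
        a2s = c2 + np.linspace(-r2, r2, 11)
        a3s = c3 + np.linspace(-r3, r3, 9)
        score = -np.inf
        for a2 in a2s:
            for a3 in a3s:
                s = _sharpness(kframe, k0, a2, a3)
                if s > score:
                    score = s
                    best = (float(a2), float(a3))
        c2, c3 = best
        r2 /= 5.0
        r3 /= 5.0
    return best


def _window(n: int, kind: str) -> np.ndarray:
    if kind == "hann":
        return np.hanning(n)
    if kind == "gaussian":
        x = np.linspace(-1.0, 1.0, n)
        return np.exp(-0.5 * (x / 0.4) ** 2)
    if kind == "none":
        return np.ones(n)
    raise ValueError(f"unknown window {kind!r}; choose from {WINDOWS}")


def reconstruct(
    frame: SpectralFrame,
    spec: SystemSpec | None = None,
    window: str = "hann",
    dispersion: tuple[float, float] | str = (0.0, 0.0),
    pad: int = 1,
) -> OctVolume:
    """Full A-scan reconstruction of one frame; returns a one-B-scan volume.

    Pipeline: remove_dc -> resample_to_k -> window -> compensate_dispersion
    -> FFT magnitude squared (positive-frequency half, linear intensity).
    The axial pixel pitch in air is derived from the wavenumber span of the
    resampled grid; ``pad`` zero-pads the FFT for sub-pixel peak sampling.
    """
    spec = spec or SystemSpec()
    kframe = resample_to_k(remove_dc(frame))
    kframe = KFrame(data=kframe.data * _window(kframe.data.shape[1], window)[None, :], k_inv_nm=kframe.k_inv_nm)
    kframe = compensate_dispersion(kframe, dispersion, k0=spec.k0_inv_nm)
    n = kframe.data.shape[1]
    spectrum = np.fft.fft(kframe.data, n=n * pad, axis=1)
    intensity = np.abs(spectrum[:, : (n * pad) // 2]) ** 2
    dz = kframe.axial_spacing_air_um(pad)
    return OctVolume(
        data=intensity[None, :, :].astype(np.float32),
        axial_spacing_um=dz,
        lateral_spacing_um=spec.lateral_spacing_um,
        meta={"kind": "reconstruction", "window": window, "pad": pad},
    )


def psf_fwhm(ascan: np.ndarray, axial_spacing_um: float) -> float:
    """FWHM (um) of the dominant intensity peak, by linear interpolation.

    Raises if no peak stands above the background floor; warns when the peak
    is narrower than two pixels (under-resolved by the sampling).
    """
    a = np.asarray(ascan, dtype=float)
    if a.ndim != 1:
        raise ValueError("psf_fwhm expects a single A-scan")
    peak = int(np.argmax(a))
    top = a[peak]
    floor = float(np.median(a))
    if top <= 0 or top <= 10.0 * max(floor, 0.0) + np.finfo(float).tiny:
        raise ValueError("no peak above the background floor")
    half = top / 2.0

    def _cross(idx_range) -> float:
        prev = peak
        for i in idx_range:
            if a[i] <= half:
                frac = (a[prev] - half) / (a[prev] - a[i])
                return prev + frac * (i - prev)
            prev = i
        return float(idx_range[-1] if len(idx_range) else peak)

    left = _cross(range(peak - 1, -1, -1))
    right = _cross(range(peak + 1, len(a)))
    width_px = right - left
    if width_px <= 2.0:
        warnings.warn(
            f"peak width {width_px:.2f} px is under-resolved by the axial sampling",
            UserWarning,
            stacklevel=2,
        )
    return float(width_px * axial_spacing_um)


def axial_resolution(
    frame: SpectralFrame,
    spec: SystemSpec | None = None,
    window: str = "none",
    dispersion: tuple[float, float] | str = (0.0, 0.0),
    pad: int = 4,
) -> float:
    """Axial resolution (um, in air) from a single-reflector frame.

    Reconstructs the frame and measures the FWHM of the modulus (amplitude)
    point-spread function, the convention under which the coherence length
    (2 ln 2 / pi) lambda_0^2 / Delta-lambda is the Gaussian-spectrum limit.
    Zero-pads the FFT for sub-pixel interpolation.
    """
    vol = reconstruct(frame, spec, window=window, dispersion=dispersion, pad=pad)
    ascan = np.sqrt(np.asarray(vol.data[0, 0], dtype=float))
    return psf_fwhm(ascan, vol.axial_spacing_um)


def in_tissue(length_air_um: float, n: float) -> float:
    """Convert an optical length in air to geometric length in a medium of index n."""
    if n < 1.0:
        raise ValueError("group refractive index must be >= 1")
    return length_air_um / n


def usaf_bar_width(group: int, element: int) -> float:
    """Single-bar width (um) of a USAF-1951 target element: 500 / 2^(g + (e-1)/6)."""
    if not 1 <= element <= 6:
        raise ValueError("USAF element must be in 1..6")
    return 500.0 / 2.0 ** (group + (element - 1) / 6.0)
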