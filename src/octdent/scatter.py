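"""Enamel scattering-coefficient estimation under single scattering.

The depth-resolved OCT signal below the surface is modeled as

    I(z) = I0 * exp(-2 mu_s z) / (1 + ((z - z_f)/z_R)^2),

single-scattering Beer-Lambert attenuation times the Lorentzian confocal
(dynamic-focusing) collection factor with focal depth z_f and Rayleigh
length z_R.  Depths z are geometric depths below the detected surface
(optical depth divided by the enamel group index), in millimeters inside the
exponent.  Surface-flattened lateral averaging of many A-scans is the
speckle-reduction step before fitting.

The fit is exposed statsmodels-style: :class:`ScatteringModel` is built from
a depth profile and ``fit()`` returns a :class:`ScatteringFit` carrying the
estimate, its diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .surface import SurfaceProfile, detect_surface
from .system import SystemSpec
from .volume import OctVolume

__all__ = [
    "confocal_factor",
    "depth_profile",
    "ScatteringModel",
    "ScatteringFit",
    "fit_mu_s",
    "scatter_volume",
]

DEFAULT_WINDOW_UM = 200.0
DEFAULT_FIT_START_UM = 10.0
MIN_FIT_SAMPLES = 10


def confocal_factor(z_um, focal_depth_um: float, rayleigh_um: float):
    """Lorentzian dynamic-focusing collection factor 1 / (1 + ((z-z_f)/z_R)^2)."""
    if rayleigh_um <= 0:
        raise ValueError("Rayleigh length must be positive")
    z_um = np.asarray(z_um, dtype=float)
    out = 1.0 / (1.0 + ((z_um - focal_depth_um) / rayleigh_um) ** 2)
    return float(out) if out.ndim == 0 else out


def depth_profile(
    bscan: np.ndarray,
    profile: SurfaceProfile,
    spec: SystemSpec,
    window_um: float = DEFAULT_WINDOW_UM,
    axial_spacing_um: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface-flattened, laterally averaged depth profile of one B-scan.

    Each unmasked A-scan is re-indexed to depth below its own surface (linear
    interpolation on the air axis), depths are converted to geometric tissue
    depth via the enamel group index, and the intensities are averaged across
    A-scans.  Returns ``(z_um below surface in tissue, mean intensity)``; the
    window is truncated with a warning where it runs off the volume.
    """
    bscan = np.asarray(bscan, dtype=float)
    m = profile.valid
    if not m.any():
        raise ValueError("no valid A-scans in the surface profile")
    if axial_spacing_um is None:
        axial_spacing_um = spec.axial_spacing_air_um

    dz_tissue = axial_spacing_um / spec.n_enamel
    z_air = np.arange(bscan.shape[1]) * axial_spacing_um
    max_depth_opt = z_air[-1] - np.max(profile.height_um[m])
    window_opt = window_um * spec.n_enamel
    if window_opt > max_depth_opt:
        warnings.warn(
            f"fit window {window_um:.0f} um exceeds the available depth; "
            f"truncated to {max_depth_opt / spec.n_enamel:.0f} um",
            UserWarning,
            stacklevel=2,
        )
        window_opt = max_depth_opt
    n_pts = int(window_opt / axial_spacing_um)
    zt = np.arange(n_pts) * dz_tissue

    acc = np.zeros(n_pts)
    for a in np.flatnonzero(m):
        query = profile.height_um[a] + zt * spec.n_enamel
        acc += np.interp(query, z_air, bscan[a])
    return zt, acc / m.sum()


@dataclass
class ScatteringFit:
    """Results of one scattering-coefficient fit."""

    mu_s_per_mm: float
    i0: float
    rsquared: float
    nobs: int
    window_um: float
    method: str
    bscan_index: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_s_per_mm):
            raise ValueError("fitted scattering coefficient is not finite")

    def summary(self) -> str:
        lines = [
            "Scattering-coefficient fit (single scattering + dynamic focusing)",
            "-" * 64,
            f"  method        : {self.method}",
            f"  mu_s          : {self.mu_s_per_mm:10.4f} mm^-1",
            f"  I0            : {self.i0:10.4g}",
            f"  R^2 (log fit) : {self.rsquared:10.4f}",
            f"  depth samples : {self.nobs:d}",
            f"  window        : {self.window_um:.0f} um below surface",
        ]
        return "\n".join(lines)


class ScatteringModel:
    """Single-scattering attenuation model for one averaged depth profile.

    Parameters
    ----------
    z_um : array
        Geometric depths below the surface (um, tissue scale).
    intensity : array
        Laterally averaged linear OCT intensity at those depths.
    focal_depth_um, rayleigh_um : float
        Confocal geometry, taken from the known optics and held fixed during
        fitting (jointly fitting them over a ~200 um window is
        ill-conditioned).
    """

    def __init__(self, z_um, intensity, focal_depth_um: float = 0.0, rayleigh_um: float = 100.0):
        self.z_um = np.asarray(z_um, dtype=float)
        self.intensity = np.asarray(intensity, dtype=float)
        if self.z_um.shape != self.intensity.shape or self.z_um.ndim != 1:
            raise ValueError("z and intensity must be matching 1-D arrays")
        if len(self.z_um) < MIN_FIT_SAMPLES:
            raise ValueError(
                f"need at least {MIN_FIT_SAMPLES} depth samples, got {len(self.z_um)}"
            )
        self.focal_depth_um = focal_depth_um
        self.rayleigh_um = rayleigh_um

    @classmethod
    def from_spec(cls, z_um, intensity, spec: SystemSpec) -> "ScatteringModel":
        return cls(z_um, intensity, spec.focal_depth_um, spec.rayleigh_um)

    def predict(self, mu_s_per_mm: float, i0: float) -> np.ndarray:
        z_mm = self.z_um * 1e-3
        return (
            i0
            * np.exp(-2.0 * mu_s_per_mm * z_mm)
            * confocal_factor(self.z_um, self.focal_depth_um, self.rayleigh_um)
        )

    def fit(self, method: str = "log-linear", bscan_index: int = 0) -> ScatteringFit:
        """Estimate (mu_s, I0); ``log-linear`` (default) or ``nonlinear``.

        log-linear divides the data by the confocal factor and fits
        ln I vs z by least squares, mu_s = -slope/2 with z in mm; nonlinear
        runs Levenberg-Marquardt on the full model seeded from a rough
        log-linear start.  R^2 is always reported on the log scale.
        """
        z_mm = self.z_um * 1e-3
        conf = confocal_factor(self.z_um, self.focal_depth_um, self.rayleigh_um)
        window = float(self.z_um[-1] - self.z_um[0])

        if method == "log-linear":
            if np.any(self.intensity <= 0):
                raise ValueError(
                    "non-positive intensities: the log-linear estimator needs "
                    "I > 0 everywhere; try method='nonlinear'"
                )
            y = np.log(self.intensity / conf)
            design = np.polynomial.polynomial.polyvander(z_mm, 1)
            coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
            if rank < 2:
                raise ValueError("singular fit: depth axis has no spread")
            intercept, slope = coef
            mu_s = -slope / 2.0
            i0 = float(np.exp(intercept))
            yhat = design @ coef
        elif method == "nonlinear":
            mask = self.intensity > 0
            if mask.sum() < MIN_FIT_SAMPLES:
                raise ValueError("too few positive intensities for a stable fit")
            rough = np.polyfit(
                z_mm[mask], np.log(self.intensity[mask] / conf[mask]), 1
            )
            p0 = (max(-rough[0] / 2.0, 0.0), float(np.exp(rough[1])))

            def model(z_um, mu_s, i0):
                return (
                    i0
                    * np.exp(-2.0 * mu_s * z_um * 1e-3)
                    * confocal_factor(z_um, self.focal_depth_um, self.rayleigh_um)
                )

            popt, _ = curve_fit(model, self.z_um, self.intensity, p0=p0, maxfev=20000)
            mu_s, i0 = float(popt[0]), float(popt[1])
            y = np.log(np.clip(self.intensity / conf, np.finfo(float).tiny, None))
            yhat = np.log(i0) - 2.0 * mu_s * z_mm
        else:
            raise ValueError("method must be 'log-linear' or 'nonlinear'")

        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return ScatteringFit(
            mu_s_per_mm=float(mu_s),
            i0=i0,
            rsquared=float(np.clip(r2, 0.0, 1.0)),
            nobs=len(self.z_um),
            window_um=window,
            method=method,
            bscan_index=bscan_index,
        )


def fit_mu_s(
    z_um,
    intensity,
    focal_depth_um: float = 0.0,
    rayleigh_um: float = 100.0,
    method: str = "log-linear",
) -> ScatteringFit:
    """Functional wrapper around :class:`ScatteringModel`."""
    return ScatteringModel(z_um, intensity, focal_depth_um, rayleigh_um).fit(method)


def scatter_volume(
    volume: OctVolume,
    spec: SystemSpec,
    window_um: float = DEFAULT_WINDOW_UM,
    fit_start_um: float = DEFAULT_FIT_START_UM,
    method: str = "log-linear",
    threshold_factor: float = 6.0,
) -> tuple[list[ScatteringFit], dict]:
    """Per-B-scan scattering fits over a volume plus a mean/SD/95%-CI summary.

    Each B-scan is surface-flattened and laterally averaged, the bright
    specular surface line is excluded by starting the fit ``fit_start_um``
    below the surface, and the fit spans the requested window of enamel.
    """
    from .report import group_stats

    fits: list[ScatteringFit] = []
    for b in range(volume.n_bscans):
        prof = detect_surface(
            volume.bscan(b),
            axial_spacing_um=volume.axial_spacing_um,
            lateral_spacing_um=volume.lateral_spacing_um,
            threshold_factor=threshold_factor,
            bscan_index=b,
        )
        zt, mean_i = depth_profile(
            volume.bscan(b),
            prof,
            spec,
            window_um=window_um,
            axial_spacing_um=volume.axial_spacing_um,
        )
        keep = zt >= fit_start_um
        if keep.sum() < MIN_FIT_SAMPLES:
            raise ValueError(
                f"window of {window_um:.0f} um leaves {int(keep.sum())} usable "
                f"depth samples; need at least {MIN_FIT_SAMPLES}"
            )
        model = ScatteringModel(
            zt[keep], mean_i[keep], spec.focal_depth_um, spec.rayleigh_um
        )
        fits.append(model.fit(method=method, bscan_index=b))
    summary = group_stats(
        [f.mu_s_per_mm for f in fits], label="mu_s", metric="mu_s_per_mm"
    ).to_dict()
    return fits, summary
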