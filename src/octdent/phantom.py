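"""Synthetic tooth phantoms with known roughness, scattering and calculus truth.

The generator emulates the statistical structure the downstream analysis
assumes: a smooth wavy enamel surface plus a zero-mean rough residual of
controlled RMS, single-scattering Beer-Lambert depth attenuation modulated by
a Lorentzian confocal factor, fully developed (unit-mean exponential)
multiplicative speckle, and an optional thin high-backscatter calculus film
with a visible lower boundary.  Raw spectral interferograms for end-to-end
reconstruction tests are synthesized from the same system description.

Everything is driven by one integer seed through named NumPy seed-sequence
sub-streams, so identical (config, seed) pairs give bit-identical volumes and
partial renders (e.g. a single B-scan) are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .system import SystemSpec, TWO_PI
from .volume import OctVolume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_surface",
    "render_volume",
    "make_phantom",
    "synthesize_interferogram",
    "preset",
    "PRESET_NAMES",
]

# sub-stream tags: stable small integers appended to the seed sequence
_STREAM_SURFACE = 0
_STREAM_SPECKLE = 1
_STREAM_FLOOR = 2
_STREAM_SHOT = 3


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one synthetic tooth volume.

    Lengths are micrometers; the axial spacing is optical path length in air.
    ``sigma_r_um`` is the target RMS of the rough surface residual after the
    smooth waviness is removed; ``mu_s_per_mm`` the enamel scattering
    coefficient; ``focal_depth_um``/``rayleigh_um`` parameterize the confocal
    (dynamic-focusing) collection factor, both measured as geometric depth
    below the surface.
    """

    n_bscans: int = 8
    n_ascans: int = 512
    n_depth: int = 300
    lateral_spacing_um: float = 1.0
    axial_spacing_um: float = 1.5
    waviness_amplitude_um: float = 10.0
    waviness_period_um: float = 500.0
    sigma_r_um: float = 1.7
    roughness_corr_um: float = 5.0
    mu_s_per_mm: float = 2.85
    surface_reflectivity: float = 1.0
    surface_depth_um: float = 80.0
    specular_gain: float = 4.0
    specular_sigma_px: float = 1.2
    focal_depth_um: float = 0.0
    rayleigh_um: float = 100.0
    n_enamel: float = 1.6
    speckle: bool = True
    noise_floor: float = 1e-4
    calculus: bool = False
    calculus_thickness_um: float | tuple = 30.0
    calculus_backscatter: float = 3.0
    n_calculus: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lateral_spacing_um",
            "axial_spacing_um",
            "waviness_period_um",
            "roughness_corr_um",
            "mu_s_per_mm",
            "rayleigh_um",
            "surface_reflectivity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma_r_um < 0:
            raise ValueError("sigma_r_um must be non-negative")
        if self.roughness_corr_um >= self.waviness_period_um:
            raise ValueError(
                "roughness correlation length must be shorter than the waviness "
                "period: the morphological filter can only separate scales that "
                "are distinct"
            )

    @property
    def depth_extent_um(self) -> float:
        return (self.n_depth - 1) * self.axial_spacing_um

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.calculus_thickness_um, tuple):
            d["calculus_thickness_um"] = list(self.calculus_thickness_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        t = d.get("calculus_thickness_um")
        if isinstance(t, list):
            d["calculus_thickness_um"] = tuple(t)
        return cls(**d)

    def system_spec(self) -> SystemSpec:
        """SystemSpec consistent with this phantom's optics."""
        return SystemSpec(
            lateral_spacing_um=self.lateral_spacing_um,
            n_enamel=self.n_enamel,
            n_calculus=self.n_calculus,
            focal_depth_um=self.focal_depth_um,
            rayleigh_um=self.rayleigh_um,
        )


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a rendered phantom.

    ``surface_um`` (air optical scale, depth from the top of the volume) is
    exactly ``waviness_um + residual_um``.  When a calculus film is present
    ``calculus_thickness_um`` holds its geometric thickness per A-scan and
    ``calculus_top_um`` the film's upper boundary on the air scale.
    """

    surface_um: np.ndarray
    waviness_um: np.ndarray
    residual_um: np.ndarray
    mu_s_per_mm: float
    calculus_thickness_um: np.ndarray | None = None
    calculus_top_um: np.ndarray | None = None

    def save(self, path) -> None:
        arrays = {
            "surface_um": self.surface_um,
            "waviness_um": self.waviness_um,
            "residual_um": self.residual_um,
            "mu_s_per_mm": np.asarray(self.mu_s_per_mm),
        }
        if self.calculus_thickness_um is not None:
            arrays["calculus_thickness_um"] = self.calculus_thickness_um
            arrays["calculus_top_um"] = self.calculus_top_um
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "PhantomTruth":
        with np.load(path) as z:
            return cls(
                surface_um=z["surface_um"],
                waviness_um=z["waviness_um"],
                residual_um=z["residual_um"],
                mu_s_per_mm=float(z["mu_s_per_mm"]),
                calculus_thickness_um=z.get("calculus_thickness_um"),
                calculus_top_um=z.get("calculus_top_um"),
            )


def _rng(config: PhantomConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _thickness_field(config: PhantomConfig) -> np.ndarray:
    """Resolve the calculus thickness spec to a (n_bscans, n_ascans) map in um."""
    spec = config.calculus_thickness_um
    shape = (config.n_bscans, config.n_ascans)
    if np.isscalar(spec):
        return np.full(shape, float(spec))
    kind = spec[0]
    if kind == "constant":
        return np.full(shape, float(spec[1]))
    if kind == "ramp":
        lo, hi = float(spec[1]), float(spec[2])
        ramp = np.linspace(lo, hi, config.n_ascans)
        return np.broadcast_to(ramp, shape).copy()
    raise ValueError(f"unknown calculus thickness spec {spec!r}")


def generate_surface(config: PhantomConfig) -> tuple[np.ndarray, PhantomTruth]:
    """Draw the tooth surface height field and its waviness/roughness split.

    The waviness is a superposition of two smooth sinusoids (along the A-scan
    axis with the configured period, plus a weaker, slower component across
    B-scans) around the mean surface depth.  The rough residual is a Gaussian
    random field band-limited to the configured correlation length and then
    renormalized so its RMS equals ``sigma_r_um`` exactly, which makes
    recovery tests sharp.  Heights are depths from the top of the volume on
    the in-air optical scale.
    """
    rng = _rng(config, _STREAM_SURFACE)
    nb, na = config.n_bscans, config.n_ascans
    x = np.arange(na) * config.lateral_spacing_um
    y = np.arange(nb) * config.lateral_spacing_um
    phi1, phi2 = rng.uniform(0.0, TWO_PI, size=2)
    a = config.waviness_amplitude_um
    wav = (
        a * np.sin(TWO_PI * x[None, :] / config.waviness_period_um + phi1)
        + 0.3 * a * np.sin(TWO_PI * y[:, None] / (2.0 * config.waviness_period_um) + phi2)
    )
    waviness = config.surface_depth_um + wav

    if config.sigma_r_um > 0:
        white = rng.standard_normal((nb, na))
        sigma_px = config.roughness_corr_um / config.lateral_spacing_um / 2.0
        rough = ndimage.gaussian_filter(white, sigma=sigma_px, mode="reflect")
        rough -= rough.mean()
        rms = float(np.sqrt(np.mean(rough**2)))
        rough *= config.sigma_r_um / rms
    else:
        rough = np.zeros((nb, na))

    surface = waviness + rough
    truth = PhantomTruth(
        surface_um=surface,
        waviness_um=waviness,
        residual_um=rough,
        mu_s_per_mm=config.mu_s_per_mm,
    )
    if config.calculus:
        t = _thickness_field(config)
        truth.calculus_thickness_um = t
        truth.calculus_top_um = surface - t * config.n_calculus
    return surface, truth


def render_volume(config: PhantomConfig, truth: PhantomTruth) -> OctVolume:
    """Render the linear-intensity volume implied by a surface truth.

    Below the surface the mean intensity follows the single-scattering model
    with dynamic focusing,

        I(z) = I0 * exp(-2 mu_s z) / (1 + ((z - z_f)/z_R)^2),

    with z the geometric depth below the surface (optical depth divided by
    the enamel group index, in mm for the exponent).  A narrow specular
    Gaussian peak marks each refractive-index interface, scaled by the local
    incident level.  Speckle, when enabled, multiplies the deterministic
    signal by i.i.d. unit-mean exponential draws (fully developed speckle);
    the detector noise floor is exponential with the configured mean.
    """
    nb, na, nd = config.n_bscans, config.n_ascans, config.n_depth
    if truth.surface_um.shape != (nb, na):
        raise ValueError("truth surface shape does not match config grid")

    z_air = np.arange(nd) * config.axial_spacing_um
    margin = 3.0 * config.specular_sigma_px * config.axial_spacing_um
    top_field = truth.calculus_top_um if config.calculus else truth.surface_um
    bad = (top_field < margin) | (truth.surface_um > config.depth_extent_um - margin)
    if np.any(bad):
        b, a = np.argwhere(bad)[0]
        raise ValueError(
            f"surface out of depth range at B-scan {b}, A-scan {a}: "
            f"height {truth.surface_um[b, a]:.1f} um (volume depth "
            f"{config.depth_extent_um:.1f} um)"
        )

    i0 = config.surface_reflectivity
    sig_px = config.specular_sigma_px * config.axial_spacing_um
    data = np.empty((nb, na, nd), dtype=np.float64)

    for b in range(nb):
        surf = truth.surface_um[b][:, None]        # (na, 1)
        depth_opt = z_air[None, :] - surf          # optical depth below surface
        zt = depth_opt / config.n_enamel           # geometric depth, um
        atten = np.exp(-2.0 * config.mu_s_per_mm * zt * 1e-3)
        conf = 1.0 / (1.0 + ((zt - config.focal_depth_um) / config.rayleigh_um) ** 2)
        film_factor = 1.0
        signal = np.where(depth_opt >= 0.0, i0 * atten * conf, 0.0)

        if config.calculus:
            top = truth.calculus_top_um[b][:, None]
            depth_c = z_air[None, :] - top
            zc = depth_c / config.n_calculus
            band = (depth_c >= 0.0) & (z_air[None, :] < surf)
            atten_c = np.exp(-2.0 * config.mu_s_per_mm * zc * 1e-3)
            conf_c = 1.0 / (1.0 + ((zc - config.focal_depth_um) / config.rayleigh_um) ** 2)
            band_i = config.calculus_backscatter * i0 * atten_c * conf_c
            signal = np.where(band, band_i, signal)
            # light reaching the tooth surface has crossed the film
            t_opt = (surf - top)
            film_tx = np.exp(-2.0 * config.mu_s_per_mm * (t_opt / config.n_calculus) * 1e-3)
            film_factor = config.calculus_backscatter * film_tx
            # specular line at the air-calculus interface
            signal = signal + (
                config.specular_gain * config.calculus_backscatter * i0
            ) * np.exp(-0.5 * ((z_air[None, :] - top) / sig_px) ** 2)

        # specular line at the (calculus-)enamel interface; rides on the
        # local illumination so it stays visible under a bright film
        signal = signal + (config.specular_gain * i0 * film_factor) * np.exp(
            -0.5 * ((z_air[None, :] - surf) / sig_px) ** 2
        )
        data[b] = signal

    if config.speckle:
        for b in range(nb):
            rng_b = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(_STREAM_SPECKLE, b))
            )
            data[b] *= rng_b.exponential(1.0, size=(na, nd))
    if config.noise_floor > 0:
        rng_f = _rng(config, _STREAM_FLOOR)
        data += rng_f.exponential(config.noise_floor, size=(nb, na, nd))

    meta = {
        "kind": "phantom",
        "config": config.to_dict(),
        "n_enamel": config.n_enamel,
        "n_calculus": config.n_calculus,
        "focal_depth_um": config.focal_depth_um,
        "rayleigh_um": config.rayleigh_um,
        "seed": config.seed,
    }
    return OctVolume(
        data=data.astype(np.float32),
        axial_spacing_um=config.axial_spacing_um,
        lateral_spacing_um=config.lateral_spacing_um,
        meta=meta,
    )


def make_phantom(config: PhantomConfig) -> tuple[OctVolume, PhantomTruth]:
    """Convenience: generate the surface and render the volume in one call."""
    _, truth = generate_surface(config)
    return render_volume(config, truth), truth


def synthesize_interferogram(
    reflector_depths_um,
    spec: SystemSpec | None = None,
    dispersion: tuple[float, float] = (0.0, 0.0),
    n_alines: int = 1,
    fringe_amplitude: float = 0.4,
    dc_level: float = 1.0,
    shot_noise: float = 0.0,
    seed: int | None = None,
):
    """Raw camera frame for point reflectors at the given depths (um, in air).

    The source envelope is Gaussian in wavelength (center ``lambda_0``, FWHM
    ``Delta-lambda``); each reflector contributes a fringe
    cos(2 k z + a2 (k-k0)^2 + a3 (k-k0)^3) with k = 2 pi / lambda, so the
    dispersion coefficients are in rad nm^2 and rad nm^3.  Returns a
    :class:`~octdent.recon.SpectralFrame` with the known reference (DC)
    spectrum attached.
    """
    from .recon import SpectralFrame  # local import to avoid a cycle

    spec = spec or SystemSpec()
    lam = spec.wavelength_axis_nm
    k = TWO_PI / lam
    k0 = spec.k0_inv_nm
    a2, a3 = dispersion

    # unambiguous-range check at the coarsest k sampling (short-wavelength end)
    dk_max = float(np.max(np.abs(np.diff(k))))
    z_max_nm = np.pi / (2.0 * dk_max)
    depths = np.atleast_1d(np.asarray(reflector_depths_um, dtype=float))
    if np.any(depths * 1e3 >= z_max_nm):
        raise ValueError(
            f"reflector depth exceeds the unambiguous range "
            f"({z_max_nm * 1e-3:.0f} um in air)"
        )
    if np.any(depths <= 0):
        raise ValueError("reflector depths must be positive")

    envelope = np.exp(-4.0 * np.log(2.0) * ((lam - spec.center_wavelength_nm) / spec.spectral_fwhm_nm) ** 2)
    fringes = np.zeros_like(lam)
    for z in depths:
        phase = 2.0 * k * (z * 1e3) + a2 * (k - k0) ** 2 + a3 * (k - k0) ** 3
        fringes = fringes + fringe_amplitude * np.cos(phase)
    line = envelope * (dc_level + fringes)
    frame = np.tile(line, (n_alines, 1))

    if shot_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed or 0, spawn_key=(_STREAM_SHOT,)))
        frame = frame + rng.normal(0.0, shot_noise, size=frame.shape) * np.sqrt(np.maximum(frame, 0.0))

    return SpectralFrame(data=frame, wavelength_nm=lam, reference=envelope * dc_level)


# Preset parameters: group means of RMS surface roughness (um) and enamel
# scattering coefficient (mm^-1) for sound enamel and the two early caries
# stages; the calculus preset is sound enamel plus a thin mineralized film.
_PRESETS = {
    "normal": dict(sigma_r_um=1.7, mu_s_per_mm=2.85),
    "caries_stage1": dict(sigma_r_um=3.7, mu_s_per_mm=4.70),
    "caries_stage2": dict(sigma_r_um=6.6, mu_s_per_mm=5.65),
    "calculus": dict(
        sigma_r_um=1.7,
        mu_s_per_mm=2.85,
        calculus=True,
        calculus_thickness_um=("ramp", 20.0, 60.0),
        surface_depth_um=150.0,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides) -> PhantomConfig:
    """Named phantom configuration for one clinical group.

    ``normal``, ``caries_stage1`` and ``caries_stage2`` set
    (sigma_r, mu_s) = (1.7 um, 2.85 mm^-1), (3.7, 4.70) and (6.6, 5.65);
    ``calculus`` is the normal tooth plus a 20-60 um film.  Keyword overrides
    (e.g. ``seed=7`` or a smaller grid) are applied on top.
    """
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(_PRESETS)}"
        ) from None
    return PhantomConfig(**{**base, **overrides})
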