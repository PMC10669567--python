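"""Tooth-surface detection and RMS roughness with morphological waviness removal.

The roughness of the air-enamel boundary is measured per B-scan: the surface
is located on every A-scan, the macroscopic form (waviness) of the tooth is
extracted with an alternating sequential grayscale morphological filter, and
the root-mean-square of the residual

    Rq = sqrt( (1/n) * sum_i z_i^2 ),    z_i = height_i - waviness_i,

is reported.  A flat structuring element of fixed physical length (70 um by
default) sets the cut between form and roughness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import OctVolume

__all__ = [
    "SurfaceProfile",
    "RoughnessResult",
    "detect_surface",
    "asf_waviness",
    "compute_rq",
    "roughness_volume",
]

DEFAULT_SE_UM = 70.0


@dataclass
class SurfaceProfile:
    """Per-A-scan surface heights (um, in-air optical depth) for one B-scan."""

    height_um: np.ndarray
    valid: np.ndarray
    lateral_spacing_um: float
    bscan_index: int = 0
    warning: str | None = None

    def __post_init__(self) -> None:
        self.height_um = np.asarray(self.height_um, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.height_um.shape != self.valid.shape:
            raise ValueError("height and validity mask must have the same shape")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class RoughnessResult:
    """Rq of one B-scan plus the waviness/residual decomposition behind it."""

    rq_um: float
    n_ascans: int
    waviness_um: np.ndarray
    residual_um: np.ndarray
    valid: np.ndarray
    se_um: float
    bscan_index: int = 0


def _first_crossing(values: np.ndarray, threshold: float) -> int | None:
    """First index where ``values`` exceeds ``threshold`` on three consecutive
    samples (a sustained crossing; isolated noise spikes do not count)."""
    above = values > threshold
    if len(above) < 3:
        hits = np.flatnonzero(above)
    else:
        hits = np.flatnonzero(above[:-2] & above[1:-1] & above[2:])
    return int(hits[0]) if hits.size else None


def _refine_subpixel(
    raw: np.ndarray, smoothed: np.ndarray, j: int, threshold: float, search_px: int = 12
) -> float:
    """Sub-pixel surface position near crossing index ``j``.

    The threshold crossing sits in the rising tail of the bright interface
    line, so the peak is sought within ``search_px`` below the crossing.  If
    the smoothed A-scan has a strict local maximum there (the specular
    surface line), return the intensity centroid over a 5-px window centered
    on it; for a plateau/step profile keep the crossing index.
    """
    n = len(raw)
    lo, hi = j, min(j + search_px, n)
    seg = smoothed[lo:hi]
    p = lo + int(np.argmax(seg))
    # peak vs step: a specular line decays after its maximum, a step plateaus
    if p + 1 >= n or not (seg.max() > smoothed[hi - 1]):
        return float(j)
    w0, w1 = max(p - 2, 0), min(p + 3, n)
    weights = np.clip(smoothed[w0:w1] - threshold, 0.0, None)
    total = weights.sum()
    if total <= 0:
        return float(p)
    return float(np.dot(np.arange(w0, w1), weights) / total)


def detect_surface(
    bscan: np.ndarray,
    axial_spacing_um: float,
    lateral_spacing_um: float = 1.0,
    threshold_factor: float = 6.0,
    smoothing: int = 3,
    lateral_smooth: int = 3,
    floor_rows: int = 8,
    despike: bool = True,
    bscan_index: int = 0,
) -> SurfaceProfile:
    """Locate the first tissue interface on every A-scan of a B-scan.

    The image is averaged over ``lateral_smooth`` neighboring A-scans (speckle
    is independent per voxel while the surface is laterally correlated, so
    this buys localization precision at a small cost in lateral bandwidth)
    and median-filtered along depth (``smoothing`` px); the noise floor mean
    and SD are estimated from the first ``floor_rows`` depth samples, and the
    surface is the first sustained crossing of floor + threshold_factor * SD,
    refined to sub-pixel by an intensity centroid.  ``despike`` runs a 3-px
    lateral median over the detected heights to remove isolated speckle
    failures.  A-scans with no crossing are masked; if more than half the
    A-scans fail, the profile carries a warning.
    """
    bscan = np.asarray(bscan, dtype=float)
    if bscan.ndim != 2 or bscan.size == 0:
        raise ValueError("detect_surface expects a non-empty 2-D (A-scan x depth) image")
    n_ascans, n_depth = bscan.shape
    floor_rows = max(2, min(floor_rows, n_depth // 4))

    if lateral_smooth > 1:
        bscan = ndimage.uniform_filter1d(bscan, size=lateral_smooth, axis=0, mode="nearest")
    sm = ndimage.median_filter(bscan, size=(1, smoothing)) if smoothing > 1 else bscan
    floor_block = sm[:, :floor_rows]
    mu = float(floor_block.mean())
    sd = float(floor_block.std())
    # the relative term keeps noise-free images from triggering on the
    # far tail of the bright interface line when the floor is exactly zero
    threshold = max(mu + threshold_factor * sd, 1e-4 * float(sm.max()))

    heights = np.full(n_ascans, np.nan)
    valid = np.zeros(n_ascans, dtype=bool)
    for a in range(n_ascans):
        j = _first_crossing(sm[a], threshold)
        if j is None:
            continue
        pos = _refine_subpixel(bscan[a], sm[a], j, threshold)
        heights[a] = pos * axial_spacing_um
        valid[a] = True

    if despike and valid.sum() >= 3:
        filled = _bridge_gaps(heights, valid)
        heights = np.where(valid, ndimage.median_filter(filled, size=3, mode="nearest"), np.nan)

    warning = None
    if valid.sum() < 0.5 * n_ascans:
        warning = (
            f"surface not found on {n_ascans - int(valid.sum())}/{n_ascans} A-scans"
        )
        warnings.warn(warning, UserWarning, stacklevel=2)
    return SurfaceProfile(
        height_um=heights,
        valid=valid,
        lateral_spacing_um=lateral_spacing_um,
        bscan_index=bscan_index,
        warning=warning,
    )


def se_length_px(se_um: float, lateral_spacing_um: float) -> int:
    """Structuring-element length as an odd pixel count (round half up)."""
    px = int(np.floor(se_um / lateral_spacing_um + 0.5))
    if px % 2 == 0:
        px += 1
    return max(px, 3)


def _bridge_gaps(height: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill masked entries by linear interpolation between valid neighbors."""
    if valid.all():
        return height.copy()
    idx = np.arange(len(height))
    return np.interp(idx, idx[valid], height[valid])


def asf_waviness(
    profile: SurfaceProfile,
    se_um: float = DEFAULT_SE_UM,
    composition: str = "average",
) -> np.ndarray:
    """Macroscopic form of the surface via an alternating sequential filter.

    Grayscale opening and closing with a flat structuring element of the
    given physical length are composed as close(open(f)) and open(close(f)).
    ``composition="average"`` (default) averages the two, which removes the
    open/close bias and makes the filter odd-symmetric (filtering -f gives
    -waviness) — the right choice for sign-symmetric roughness.
    ``"open-close"`` / ``"close-open"`` select one branch; open-close is
    preferable when artifacts are one-sided bright spikes, which a leading
    closing can bridge when they sit closer together than the element.
    Masked gaps are bridged by linear interpolation before filtering and the
    output is valid everywhere the input was; boundaries use edge
    replication.
    """
    if se_um <= 2.0 * profile.lateral_spacing_um:
        raise ValueError(
            "structuring element must be longer than twice the lateral spacing"
        )
    n = len(profile.height_um)
    px = se_length_px(se_um, profile.lateral_spacing_um)
    if px > n:
        raise ValueError(
            f"structuring element ({px} px) longer than the profile ({n} px)"
        )
    if profile.n_valid == 0:
        raise ValueError("cannot filter a fully masked profile")
    f = _bridge_gaps(profile.height_um, profile.valid)
    mode = "nearest"
    oc = ndimage.grey_closing(ndimage.grey_opening(f, size=px, mode=mode), size=px, mode=mode)
    if composition == "open-close":
        return oc
    co = ndimage.grey_opening(ndimage.grey_closing(f, size=px, mode=mode), size=px, mode=mode)
    if composition == "close-open":
        return co
    if composition != "average":
        raise ValueError("composition must be 'average', 'open-close' or 'close-open'")
    return 0.5 * (oc + co)


def compute_rq(profile: SurfaceProfile, waviness_um: np.ndarray, se_um: float = DEFAULT_SE_UM) -> RoughnessResult:
    """RMS roughness of the waviness-removed residual over unmasked A-scans."""
    waviness_um = np.asarray(waviness_um, dtype=float)
    if waviness_um.shape != profile.height_um.shape:
        raise ValueError("waviness profile must align with the surface profile")
    m = profile.valid
    n = int(m.sum())
    if n < 10:
        raise ValueError(f"need at least 10 unmasked A-scans to compute Rq, got {n}")
    residual = np.where(m, profile.height_um - waviness_um, np.nan)
    rq = float(np.sqrt(np.nanmean(residual[m] ** 2)))
    return RoughnessResult(
        rq_um=rq,
        n_ascans=n,
        waviness_um=waviness_um,
        residual_um=residual,
        valid=m.copy(),
        se_um=se_um,
        bscan_index=profile.bscan_index,
    )


def roughness_volume(
    volume: OctVolume,
    se_um: float = DEFAULT_SE_UM,
    threshold_factor: float = 6.0,
    smoothing: int = 3,
) -> tuple[list[RoughnessResult], dict]:
    """Per-B-scan Rq over a volume plus a mean/SD/95%-CI summary.

    The confidence interval is a Student-t interval across B-scans; with a
    single B-scan the CI is undefined and flagged as NaN.
    """
    from .report import group_stats

    if volume.n_bscans < 1:
        raise ValueError("volume has no B-scans")
    results: list[RoughnessResult] = []
    for b in range(volume.n_bscans):
        try:
            prof = detect_surface(
                volume.bscan(b),
                axial_spacing_um=volume.axial_spacing_um,
                lateral_spacing_um=volume.lateral_spacing_um,
                threshold_factor=threshold_factor,
                smoothing=smoothing,
                bscan_index=b,
            )
            wav = asf_waviness(prof, se_um=se_um)
            results.append(compute_rq(prof, wav, se_um=se_um))
        except ValueError:
            continue
    if not results:
        raise ValueError("surface detection failed on every B-scan of the volume")
    summary = group_stats([r.rq_um for r in results], label="Rq", metric="Rq_um").to_dict()
    return results, summary
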