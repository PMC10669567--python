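"""Calculus film segmentation and thickness mapping.

Dental calculus appears in OCT as a thin high-backscatter film on top of the
enamel, with a bright line at the calculus-enamel boundary underneath.  Per
A-scan, the film's upper surface is the first threshold crossing (as in
plain surface detection) and the tooth surface underneath is the next
prominent local intensity maximum; the optical distance between the two,
divided by the calculus group index, is the film thickness.  Repeating this
over a 3-D dataset yields the thickness distribution map.
"""

from __future__ import annotations

import warnings

import numpy as np
from dataclasses import dataclass
from scipy import ndimage
from scipy.signal import find_peaks

from .surface import _first_crossing, _refine_subpixel
from .system import SystemSpec
from .volume import OctVolume

__all__ = ["ThicknessMap", "detect_two_surfaces", "thickness_map"]

MIN_SEPARATION_PX = 4
MIN_VALID_FRACTION = 0.05


@dataclass
class ThicknessMap:
    """Calculus thickness (um, geometric) over the (B-scan x A-scan) grid.

    ``thickness_um`` is the 3x3-median-filtered map with NaN where either
    interface was not detected; ``raw_um`` keeps the unfiltered values.
    """

    thickness_um: np.ndarray
    raw_um: np.ndarray
    valid: np.ndarray
    n_calculus: float
    top_um: np.ndarray = None
    bottom_um: np.ndarray = None

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def summary(self) -> dict:
        vals = self.thickness_um[self.valid & np.isfinite(self.thickness_um)]
        return {
            "n_valid": int(vals.size),
            "mean_um": float(np.mean(vals)),
            "sd_um": float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
            "p5_um": float(np.percentile(vals, 5)),
            "p50_um": float(np.percentile(vals, 50)),
            "p95_um": float(np.percentile(vals, 95)),
            "n_calculus": self.n_calculus,
        }

    def histogram(self, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        """Thickness histogram; counts sum to the number of valid A-scans."""
        vals = self.thickness_um[self.valid & np.isfinite(self.thickness_um)]
        return np.histogram(vals, bins=bins)


def detect_two_surfaces(
    ascan: np.ndarray,
    axial_spacing_um: float,
    threshold: float,
    smoothing: int = 3,
    prominence_factor: float = 1.0,
    min_separation_px: int = MIN_SEPARATION_PX,
) -> tuple[float | None, float | None]:
    """Locate the calculus top and the underlying tooth surface on one A-scan.

    Returns (top_um, bottom_um) on the in-air optical depth scale; either may
    be None.  The top is the first sustained threshold crossing refined by a
    sub-pixel centroid.  The bottom is the first local maximum at least
    ``min_separation_px`` below the top whose prominence exceeds
    ``prominence_factor`` times the local background level — a criterion
    robust to speckle, unlike a second threshold re-crossing.
    """
    raw = np.asarray(ascan, dtype=float)
    sm = ndimage.median_filter(raw, size=smoothing) if smoothing > 1 else raw

    j = _first_crossing(sm, threshold)
    if j is None:
        return None, None
    top_px = _refine_subpixel(raw, sm, j, threshold)
    top_um = top_px * axial_spacing_um

    start = int(round(top_px)) + min_separation_px
    if start >= len(sm) - 2:
        return top_um, None
    seg = sm[start:]
    peaks, _ = find_peaks(seg)
    if peaks.size == 0:
        return top_um, None
    prominences = _peak_prominences(seg, peaks)

    # reference level: the enamel just below each candidate.  The interface
    # line brightens with the film's backscatter while the enamel underneath
    # does not, so the detection margin grows with film contrast; speckle
    # bumps riding on the film or the enamel stay near their own level.
    bg = np.empty(peaks.size)
    for i, p in enumerate(peaks):
        block = seg[p + 3 : p + 18]
        bg[i] = np.median(block) if block.size >= 5 else np.median(seg[max(p - 7, 0) : p + 8])
    bg = np.maximum(bg, np.finfo(float).tiny)

    good = (seg[peaks] >= 2.0 * bg) & (prominences >= prominence_factor * bg)
    peaks, bg = peaks[good], bg[good]
    if peaks.size == 0:
        return top_um, None
    # the interface line is the brightest feature relative to its substrate
    sel = int(np.argmax(seg[peaks] / bg))
    p = start + int(peaks[sel])
    w0, w1 = max(p - 2, 0), min(p + 3, len(raw))
    weights = np.clip(sm[w0:w1] - float(bg[sel]), 0.0, None)
    if weights.sum() > 0:
        bottom_px = float(np.dot(np.arange(w0, w1), weights) / weights.sum())
    else:
        bottom_px = float(p)
    return top_um, bottom_px * axial_spacing_um


def _peak_prominences(seg: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    from scipy.signal import peak_prominences

    if peaks.size == 0:
        return np.empty(0)
    return peak_prominences(seg, peaks)[0]


def _detection_threshold(sm: np.ndarray, threshold_factor: float, floor_rows: int) -> float:
    block = sm[:, :floor_rows]
    return float(block.mean() + threshold_factor * block.std())


def thickness_map(
    volume: OctVolume,
    spec: SystemSpec | None = None,
    n_calculus: float | None = None,
    threshold_factor: float = 6.0,
    smoothing: int = 3,
    lateral_smooth: int = 5,
    prominence_factor: float = 1.0,
    consistency_um: float = 5.0,
) -> ThicknessMap:
    """Segment the calculus film over a whole volume.

    Each B-scan is lightly smoothed laterally (``lateral_smooth`` A-scans)
    to tame speckle before the per-A-scan two-interface search; thickness is
    (bottom - top) optical distance divided by the calculus group index.
    Detections whose thickness deviates more than ``consistency_um`` from the
    local 5x5 median, or with fewer than half their neighbors detected, are
    rejected as speckle artifacts, and the map is cleaned with a mask-aware
    3x3 median filter (the raw map is retained).  Raises when fewer than 5%
    of A-scans show two interfaces.
    """
    spec = spec or SystemSpec()
    if n_calculus is None:
        n_calculus = spec.n_calculus

    nb, na = volume.n_bscans, volume.n_ascans
    top = np.full((nb, na), np.nan)
    bottom = np.full((nb, na), np.nan)
    for b in range(nb):
        img = np.asarray(volume.bscan(b), dtype=float)
        if lateral_smooth > 1:
            img = ndimage.uniform_filter1d(img, size=lateral_smooth, axis=0, mode="nearest")
        sm = ndimage.median_filter(img, size=(1, smoothing)) if smoothing > 1 else img
        floor_rows = max(2, min(8, volume.n_depth // 4))
        threshold = _detection_threshold(sm, threshold_factor, floor_rows)
        for a in range(na):
            t, bo = detect_two_surfaces(
                img[a],
                axial_spacing_um=volume.axial_spacing_um,
                threshold=threshold,
                smoothing=smoothing,
                prominence_factor=prominence_factor,
            )
            if t is not None:
                top[b, a] = t
            if bo is not None:
                bottom[b, a] = bo

    valid = np.isfinite(top) & np.isfinite(bottom) & (bottom > top)
    # a real film is laterally contiguous with a locally smooth thickness;
    # speckle false alarms are isolated and land at random depths
    if valid.any():
        opt_thick = np.where(valid, bottom - top, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            local_med = ndimage.generic_filter(opt_thick, np.nanmedian, size=5, mode="nearest")
        valid &= np.abs(opt_thick - local_med) <= consistency_um * n_calculus
        neighbor_frac = ndimage.uniform_filter(valid.astype(float), size=3, mode="constant")
        valid &= neighbor_frac >= 0.5
    if valid.sum() < MIN_VALID_FRACTION * nb * na:
        raise ValueError(
            "no calculus layer detected: a second interface was found on "
            f"{valid.sum()} of {nb * na} A-scans"
        )
    raw = np.where(valid, (bottom - top) / n_calculus, np.nan)

    # mask-aware 3x3 median: fill gaps with the local valid median first
    filled = raw.copy()
    if not valid.all():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = ndimage.generic_filter(
                np.where(valid, raw, np.nan), np.nanmedian, size=3, mode="nearest"
            )
        filled = np.where(valid, raw, med)
    smooth = ndimage.median_filter(filled, size=3, mode="nearest")
    smooth = np.where(valid, smooth, np.nan)

    return ThicknessMap(
        thickness_um=smooth,
        raw_um=raw,
        valid=valid,
        n_calculus=float(n_calculus),
        top_um=top,
        bottom_um=bottom,
    )
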