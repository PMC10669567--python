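"""In-memory OCT volume container and its TIFF + JSON disk dialect.

A volume is a 3-D linear-intensity array indexed (B-scan, A-scan, depth).
On disk it is a multi-page 32-bit float TIFF (one page per B-scan, page shape
A-scans x depth) next to a JSON sidecar holding the physical pixel spacings
and provenance metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class OctVolume:
    """3-D linear-intensity OCT volume with physical pixel spacings.

    ``data`` has shape (n_bscans, n_ascans, n_depth); ``axial_spacing_um`` is
    the depth pitch measured in air (optical path length), so geometric depth
    inside a medium of group index n is (pixels * axial_spacing_um) / n.
    """

    data: np.ndarray
    axial_spacing_um: float
    lateral_spacing_um: float
    bscan_spacing_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D (B-scan, A-scan, depth) array, got shape {self.data.shape}")
        if self.axial_spacing_um <= 0 or self.lateral_spacing_um <= 0:
            raise ValueError("pixel spacings must be positive")
        if self.bscan_spacing_um is None:
            self.bscan_spacing_um = self.lateral_spacing_um

    @property
    def n_bscans(self) -> int:
        return self.data.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.data.shape[1]

    @property
    def n_depth(self) -> int:
        return self.data.shape[2]

    @property
    def depth_axis_um(self) -> np.ndarray:
        """Depth coordinate of each pixel in air (um)."""
        return np.arange(self.n_depth) * self.axial_spacing_um

    def bscan(self, index: int) -> np.ndarray:
        """One cross-sectional image, shape (n_ascans, n_depth)."""
        return self.data[index]

    def save(self, path: str | Path) -> Path:
        """Write multi-page float32 TIFF plus a ``.json`` sidecar; returns the TIFF path."""
        path = Path(path)
        tifffile.imwrite(path, self.data, photometric="minisblack")
        sidecar = {
            "axial_spacing_um": self.axial_spacing_um,
            "lateral_spacing_um": self.lateral_spacing_um,
            "bscan_spacing_um": self.bscan_spacing_um,
            "shape": list(self.data.shape),
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "OctVolume":
        path = Path(path)
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data=data,
            axial_spacing_um=sidecar["axial_spacing_um"],
            lateral_spacing_um=sidecar["lateral_spacing_um"],
            bscan_spacing_um=sidecar.get("bscan_spacing_um"),
            meta=sidecar.get("meta", {}),
        )


def _jsonable(obj):
    """Best-effort conversion of metadata to JSON-serializable types."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
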