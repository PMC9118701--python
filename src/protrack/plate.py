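"""Plate discovery and TIFF input/output.

Time-lapse frames are stored one grayscale TIFF per well per time point,
named ``<well>_TP<k>.tif`` with k a 1-based time-point index; TPk maps to
DAI(k-1) (days after immobilization).  Well ids are treated as opaque
tokens.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["PlateLayout", "discover_plate", "read_frame"]

log = logging.getLogger(__name__)

_PATTERN = re.compile(r"^(?P<well>.+)_TP(?P<tp>\d+)\.tiff?$", re.IGNORECASE)


@dataclass
class PlateLayout:
    """Wells mapped to chronologically ordered frame paths."""

    wells: dict[str, list[Path]]
    pixel_size: float = 1.0
    gaps: dict[str, list[int]] = field(default_factory=dict)

    def timepoints(self, well: str) -> int:
        return len(self.wells[well])


def discover_plate(directory: str | Path, pixel_size: float = 1.0) -> PlateLayout:
    """Group a directory of ``<well>_TP<k>.tif`` files into a plate layout.

    Non-matching files are ignored with a warning; duplicate (well, TP)
    pairs and directories without any matching file are errors.  Missing
    intermediate time points are reported in ``gaps``.
    """
    directory = Path(directory)
    found: dict[str, dict[int, Path]] = {}
    for path in sorted(directory.rglob("*.tif")) + sorted(directory.rglob("*.tiff")):
        m = _PATTERN.match(path.name)
        if not m:
            log.warning("ignoring non-matching file %s", path.name)
            continue
        well, tp = m.group("well"), int(m.group("tp"))
        if tp in found.setdefault(well, {}):
            raise ValueError(f"duplicate frame for well {well!r} TP{tp}: {path}")
        found[well][tp] = path
    if not found:
        raise FileNotFoundError(f"no files matching '<well>_TP<k>.tif' under {directory}")
    wells = {}
    gaps = {}
    for well, frames in sorted(found.items()):
        tps = sorted(frames)
        missing = sorted(set(range(1, tps[-1] + 1)) - set(tps))
        if missing:
            gaps[well] = missing
            log.warning("well %s is missing time points %s", well, missing)
        wells[well] = [frames[t] for t in tps]
    return PlateLayout(wells=wells, pixel_size=pixel_size, gaps=gaps)


def read_frame(path: str | Path) -> np.ndarray:
    """Read one grayscale frame as a float image in [0, 1]."""
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {img.shape}")
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(float) / float(np.iinfo(img.dtype).max)
    return img.astype(float)
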