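"""Flat pipeline configuration with validated, documented defaults.

One config object governs every stage; defaults are the pipeline's
standard operating point (local-contrast block radius 90 px at 1 std,
0.8% saturated stretch, bandpass structure sizes 3-100 px with 5%
horizontal-stripe tolerance, 27 um tracking shift threshold, 4000 px
microcalli threshold).  Configs load from flat dotted-key YAML, e.g.
``preproc.block_radius: 90``, and serialize back for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]

# dotted config key -> dataclass field
_KEYMAP = {
    "pixel_size": "pixel_size",
    "preproc.block_radius": "block_radius",
    "preproc.stds": "stds",
    "preproc.center": "center",
    "preproc.saturated": "saturated",
    "preproc.filter_large": "filter_large",
    "preproc.filter_small": "filter_small",
    "preproc.suppress": "suppress",
    "preproc.tolerance": "tolerance",
    "preproc.align.search_px": "align_search_px",
    "preproc.align.reference": "align_reference",
    "segment.backend": "backend",
    "segment.sigma": "segment_sigma",
    "segment.polarity": "polarity",
    "segment.opening_radius": "opening_radius",
    "segment.min_cell_area": "min_cell_area",
    "watershed.min_seed_sep": "min_seed_sep",
    "watershed.h_depth": "h_depth",
    "cluster.min_fragment_area": "min_fragment_area",
    "tracking.max_shift_um": "max_shift_um",
    "stats.bin_width_um2": "bin_width_um2",
    "stats.proliferation_threshold_px": "proliferation_threshold_px",
}
_FIELD_TO_KEY = {v: k for k, v in _KEYMAP.items()}


@dataclass
class PipelineConfig:
    pixel_size: float = 1.0  # um per pixel edge

    # preprocessing
    block_radius: int = 90
    stds: float = 1.0
    center: bool = True
    saturated: float = 0.8
    filter_large: float = 100.0
    filter_small: float = 3.0
    suppress: str | None = "horizontal"
    tolerance: float = 5.0
    align_search_px: int = 20
    align_reference: int = 0

    # segmentation and post-processing
    backend: str = "reference"
    segment_sigma: float = 1.5
    polarity: str = "bright"
    opening_radius: int = 2
    min_cell_area: int = 50
    min_seed_sep: float = 5.0
    h_depth: float = 0.5
    min_fragment_area: int = 20

    # tracking and statistics
    max_shift_um: float = 27.0
    bin_width_um2: float = 100.0
    proliferation_threshold_px: int = 4000

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.block_radius < 1:
            raise ValueError("preproc.block_radius must be >= 1")
        if not (0 <= self.saturated < 100):
            raise ValueError("preproc.saturated must lie in [0, 100)")
        if not (0 < self.filter_small < self.filter_large):
            raise ValueError("need 0 < preproc.filter_small < preproc.filter_large")
        if self.align_search_px < 1:
            raise ValueError("preproc.align.search_px must be >= 1")
        if self.polarity not in ("bright", "dark"):
            raise ValueError("segment.polarity must be 'bright' or 'dark'")
        if self.min_cell_area < 0 or self.min_fragment_area < 0:
            raise ValueError("area thresholds must be non-negative")
        if self.max_shift_um <= 0:
            raise ValueError("tracking.max_shift_um must be positive")
        if self.bin_width_um2 <= 0:
            raise ValueError("stats.bin_width_um2 must be positive")
        if self.proliferation_threshold_px <= 0:
            raise ValueError("stats.proliferation_threshold_px must be positive")
        if isinstance(self.suppress, str) and self.suppress.lower() in ("none", ""):
            self.suppress = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a flat key-value mapping")
        kwargs = {}
        for key, value in raw.items():
            if key not in _KEYMAP:
                raise KeyError(f"unknown config key {key!r}")
            kwargs[_KEYMAP[key]] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        """Write the effective configuration next to outputs for provenance."""
        flat = {_FIELD_TO_KEY[f.name]: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))

    def replace(self, **kwargs) -> "PipelineConfig":
        data = asdict(self)
        data.update(kwargs)
        return PipelineConfig(**data)
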