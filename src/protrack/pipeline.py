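"""End-to-end orchestration: frames in, tracked-lineage statistics out.

Per well: align the chronological stack, preprocess (tile, contrast,
bandpass, stitch), segment each frame with the configured backend, fill
holes, watershed-split, remove contacting-cell clusters and
frame-truncated objects, measure regions, match consecutive day pairs by
centroid distance, chain lineages from DAI0, and compute growth/response
statistics.  Every stage logs object counts, and the per-frame ledger sums
exactly: segmented = retained + cluster-removed + border-removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from . import preproc, segment, stats, tracking
from .config import PipelineConfig
from .plate import PlateLayout, read_frame

__all__ = ["FrameResult", "WellResult", "PipelineResult", "process_frames", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class FrameResult:
    timepoint: int
    labels: np.ndarray  # retained single-cell label map
    records: pd.DataFrame
    n_original: int
    n_cluster_removed: int
    n_border_removed: int

    @property
    def n_retained(self) -> int:
        return len(self.records)


@dataclass
class WellResult:
    well: str
    frames: list[FrameResult]
    matchsets: list[tracking.MatchSet]
    lineages: list[tracking.Lineage]
    lineage_tbl: pd.DataFrame
    counts: pd.DataFrame  # per-frame filtration ledger
    alignment: preproc.AlignmentResult | None = None

    def growth(self, target_dai: int) -> pd.DataFrame:
        return stats.growth_rates(self.lineage_tbl, target_dai)

    def response(self, target_dai: int) -> stats.ResponseSummary:
        return stats.response_ratio(self.growth(target_dai))

    def intervals(self) -> pd.DataFrame:
        return stats.interval_changes(self.lineage_tbl)


@dataclass
class PipelineResult:
    wells: dict[str, WellResult] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str | Path, config: PipelineConfig | None = None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for well, res in sorted(self.wells.items()):
            recs = pd.concat([f.records for f in res.frames], ignore_index=True)
            recs.to_csv(out_dir / f"{well}_records.csv", index=False)
            res.lineage_tbl.to_csv(out_dir / f"{well}_lineages.csv", index=False)
            res.counts.to_csv(out_dir / f"{well}_counts.csv", index=False)
            res.intervals().to_csv(out_dir / f"{well}_intervals.csv", index=False)
        if config is not None:
            config.to_yaml(out_dir / "effective_config.yaml")


def _segment_frame(image: np.ndarray, cfg: PipelineConfig, well: str, t: int) -> FrameResult:
    if cfg.backend == "reference":
        mask = segment.segment_reference(
            image,
            sigma=cfg.segment_sigma,
            polarity=cfg.polarity,
            opening_radius=cfg.opening_radius,
            min_cell_area=cfg.min_cell_area,
        )
    else:
        mask = segment.run_backend(cfg.backend, image)
    mask = segment.fill_holes(mask)
    original = cc_label(mask, connectivity=2).astype(np.int32)
    split = segment.watershed_split(mask, min_seed_sep=cfg.min_seed_sep, h_depth=cfg.h_depth)
    kept, removed = segment.filter_clusters(original, split, min_fragment_area=cfg.min_fragment_area)
    n_after_cluster = int(kept.max())
    final = segment.exclude_border(kept)
    records = segment.measure_regions(final, pixel_size=cfg.pixel_size, well=well, timepoint=t)
    return FrameResult(
        timepoint=t,
        labels=final,
        records=records,
        n_original=int(original.max()),
        n_cluster_removed=len(removed),
        n_border_removed=n_after_cluster - int(final.max()),
    )


def process_frames(
    images: list[np.ndarray],
    cfg: PipelineConfig | None = None,
    well: str = "1B",
    align: bool = True,
    preprocess: bool = True,
) -> WellResult:
    """Run the full analysis chain on an in-memory chronological stack."""
    cfg = cfg or PipelineConfig()
    alignment = None
    if align and len(images) >= 2:
        images, alignment = preproc.align_slices(
            images, reference_index=cfg.align_reference, search_px=cfg.align_search_px
        )
    if preprocess:
        images = preproc.preprocess_well(
            images,
            block_radius=cfg.block_radius,
            stds=cfg.stds,
            center=cfg.center,
            saturated_percent=cfg.saturated,
            filter_large=cfg.filter_large,
            filter_small=cfg.filter_small,
            suppress=cfg.suppress,
            tolerance_percent=cfg.tolerance,
        )
    frames = [_segment_frame(img, cfg, well, t) for t, img in enumerate(images)]
    for f in frames:
        log.info(
            "well %s DAI%d: %d segmented = %d retained + %d clusters + %d border",
            well,
            f.timepoint,
            f.n_original,
            f.n_retained,
            f.n_cluster_removed,
            f.n_border_removed,
        )
    counts = pd.DataFrame(
        [
            (well, f.timepoint, f.n_original, f.n_retained, f.n_cluster_removed, f.n_border_removed)
            for f in frames
        ],
        columns=["well", "timepoint", "n_original", "n_retained", "n_cluster_removed", "n_border_removed"],
    )
    matchsets = [
        tracking.match_cells(frames[t].records, frames[t + 1].records, max_shift_um=cfg.max_shift_um)
        for t in range(len(frames) - 1)
    ]
    labels_t0 = frames[0].records["label"].tolist()
    lineages = tracking.build_lineages(matchsets, labels_t0)
    tbl = tracking.lineage_table(lineages, [f.records for f in frames])
    return WellResult(
        well=well,
        frames=frames,
        matchsets=matchsets,
        lineages=lineages,
        lineage_tbl=tbl,
        counts=counts,
        alignment=alignment,
    )


def run_pipeline(layout: PlateLayout, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run every well of a plate; a failing well is logged and skipped."""
    cfg = cfg or PipelineConfig(pixel_size=layout.pixel_size)
    result = PipelineResult()
    for well, paths in layout.wells.items():
        try:
            images = [read_frame(p) for p in paths]
            shapes = {img.shape for img in images}
            if len(shapes) > 1:
                raise ValueError(f"well {well}: frames have differing shapes {shapes}")
            result.wells[well] = process_frames(images, cfg, well=well)
        except Exception as exc:  # noqa: BLE001 - other wells continue
            log.error("well %s aborted: %s", well, exc)
            result.failures[well] = str(exc)
    return result
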