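"""Synthetic full-well time-lapse generator with per-cell ground truth.

Emulates daily bright-field recordings of wall-less plant protoplasts
immobilized in a multi-well plate: quasi-circular cells (diameters roughly
15-40 um) rendered as anti-aliased disks that grow or shrink by a fixed
per-interval area factor, jitter slightly in position between recordings,
and optionally sit in contact as clusters.  Every rendered cell carries
ground truth (position, radius, growth factor, cluster membership) so the
downstream segmentation, tracking and statistics stages can be tested
without microscope data.

Images are 2-D float arrays in [0, 1]; positions and radii are in um and
converted to pixels via ``pixel_size`` (um per pixel edge).  x is the
column index, y the row index, origin at the top-left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SimulatedCell",
    "SimulationSpec",
    "GroundTruth",
    "PlacementError",
    "render_cell",
    "simulate_plate",
    "write_plate",
]

#: columns of the ground-truth table, one row per rendered cell per time point
TRUTH_COLUMNS = [
    "cell_id",
    "timepoint",
    "cx_um",
    "cy_um",
    "radius_um",
    "area_um2",
    "growth_factor",
    "cluster_group",
    "is_cluster",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed under the spacing constraint."""


@dataclass(frozen=True)
class SimulatedCell:
    """One simulated protoplast with its full truth parameterization."""

    cell_id: int
    center0: tuple[float, float]  # (x, y) um at time 0
    radius0: float  # um
    growth_factor: float  # per-interval area multiplier
    drift_sigma: float  # um, std of per-interval positional jitter
    intensity: float  # cell/background contrast in [0, 1]
    cluster_group: int = -1  # -1 = isolated

    def __post_init__(self) -> None:
        if self.radius0 <= 0:
            raise ValueError("radius0 must be positive")
        if self.growth_factor <= 0:
            raise ValueError("growth_factor must be positive")

    def radius_at(self, t: int) -> float:
        """Radius at time point *t* under the area law A_t = A_0 * g**t."""
        return self.radius0 * self.growth_factor ** (t / 2.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic well.

    Defaults emulate a scaled-down well: 300 cells at 60 um hard-core
    spacing (real wells hold ~8000 protoplasts; the density here keeps
    rejection sampling cheap while preserving the tracking geometry),
    40% of cells growing at a 1.2x per-interval area factor and the rest
    shrinking at 0.9x, 5 um positional jitter per interval, four daily
    time points (DAI0..DAI3).
    """

    image_shape: tuple[int, int] = (1700, 1700)  # (rows, cols) px
    pixel_size: float = 1.0  # um per pixel edge
    n_timepoints: int = 4
    n_cells: int = 300
    fraction_growing: float = 0.4
    grow_factor: float = 1.2
    shrink_factor: float = 0.9
    radius_range_um: tuple[float, float] = (7.5, 20.0)
    min_spacing: float = 60.0  # um between non-cluster cell centers
    drift_sigma: float = 5.0  # um per interval
    noise_sigma: float = 0.02  # additive intensity noise std
    stripe_amplitude: float = 0.0  # horizontal-stripe artifact amplitude
    stripe_period: float = 40.0  # px, stripe period along y
    global_shift: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px per time point
    cluster_fraction: float = 0.0  # fraction of cells placed in contact
    cluster_size: int = 2
    background: float = 0.2
    cell_intensity: float = 0.75
    edge_margin_um: float | None = None  # None -> derived from radii and drift
    max_place_tries: int = 200  # rejection-sampling retries per cell
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not (0.0 <= self.fraction_growing <= 1.0):
            raise ValueError("fraction_growing must lie in [0, 1]")
        if self.grow_factor <= 0 or self.shrink_factor <= 0:
            raise ValueError("growth factors must be positive")
        if self.radius_range_um[0] <= 0 or self.radius_range_um[1] < self.radius_range_um[0]:
            raise ValueError("radius_range_um must be positive and ordered")
        if self.cluster_size < 2:
            raise ValueError("cluster_size must be >= 2")

    @property
    def n_dais(self) -> int:
        return self.n_timepoints


@dataclass
class GroundTruth:
    """Per-cell, per-time-point truth for one simulated well.

    ``table`` has one row per rendered cell per time point (TRUTH_COLUMNS);
    cell identity is persistent across time points, so the matching map
    between consecutive frames is the identity on cell_id.
    """

    table: pd.DataFrame
    spec: SimulationSpec
    cells: list[SimulatedCell] = field(default_factory=list)

    def frame(self, t: int) -> pd.DataFrame:
        return self.table[self.table["timepoint"] == t].reset_index(drop=True)

    def matching(self, t: int) -> dict[int, int]:
        """Truth correspondence between time points t and t+1 (a bijection)."""
        a = set(self.frame(t)["cell_id"])
        b = set(self.frame(t + 1)["cell_id"])
        return {i: i for i in sorted(a & b)}

    def label_map(self, t: int) -> np.ndarray:
        """Rasterized truth labels at time t (label = cell_id, 0 = background)."""
        shape = self.spec.image_shape
        lab = np.zeros(shape, dtype=np.int32)
        px = self.spec.pixel_size
        for row in self.frame(t).itertuples():
            _paint_disk_label(lab, (row.cx_um / px, row.cy_um / px), row.radius_um / px, int(row.cell_id))
        return lab

    def mask(self, t: int) -> np.ndarray:
        return self.label_map(t) > 0

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _disk_window(image_shape, cx, cy, radius):
    r0 = max(int(math.floor(cy - radius - 1.0)), 0)
    r1 = min(int(math.ceil(cy + radius + 2.0)), image_shape[0])
    c0 = max(int(math.floor(cx - radius - 1.0)), 0)
    c1 = min(int(math.ceil(cx + radius + 2.0)), image_shape[1])
    return r0, r1, c0, c1


def _paint_disk_label(labels: np.ndarray, center_px, radius_px: float, label: int) -> None:
    cx, cy = center_px
    r0, r1, c0, c1 = _disk_window(labels.shape, cx, cy, radius_px)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
    labels[r0:r1, c0:c1][inside] = label


def render_cell(
    image: np.ndarray,
    center_um: tuple[float, float],
    radius_um: float,
    intensity: float,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Render one anti-aliased disk into a copy of *image*.

    Pixels whose centers fall inside the disk are blended toward
    ``intensity``; a 1-px rim gets partial coverage so measured areas track
    pi*r^2 closely.  Portions outside the frame are silently clipped, and
    repeated/overlapping calls never push values beyond ``intensity``.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    out = np.array(image, dtype=float, copy=True)
    _render_cell_inplace(out, center_um, radius_um, intensity, pixel_size)
    return out


def _render_cell_inplace(image, center_um, radius_um, intensity, pixel_size) -> None:
    cx = center_um[0] / pixel_size
    cy = center_um[1] / pixel_size
    r = radius_um / pixel_size
    r0, r1, c0, c1 = _disk_window(image.shape, cx, cy, r)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(xx - cx, yy - cy)
    cov = np.clip(r + 0.5 - d, 0.0, 1.0)
    patch = image[r0:r1, c0:c1]
    patch += cov * (intensity - patch)


def _sample_group(rng, spec: SimulationSpec, radii, group_id):
    """Relative member offsets for a cluster group (touching footprints)."""
    offsets = [np.zeros(2)]
    for k in range(1, len(radii)):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        # overlap by 15% of the summed radii so watershed sees one object
        d = 0.8 * (radii[k - 1] + radii[k])
        offsets.append(offsets[k - 1] + d * np.array([math.cos(theta), math.sin(theta)]))
    return np.array(offsets)


def _place_cells(spec: SimulationSpec, rng: np.random.Generator):
    """Rejection-sample cell trajectories under the hard-core spacing rule.

    Returns (cells, traj) where traj[i, t] is the (x, y) um position of cell
    i at time point t, excluding the global frame shift (which is common to
    all cells and cannot affect spacing).
    """
    n = spec.n_cells
    T = spec.n_timepoints
    rows, cols = spec.image_shape
    h_um = rows * spec.pixel_size
    w_um = cols * spec.pixel_size

    n_groups = int(round(spec.cluster_fraction * n / spec.cluster_size))
    n_clustered = n_groups * spec.cluster_size
    if n_clustered > n:
        raise ValueError("cluster_fraction/cluster_size exceed n_cells")

    gmax = max(spec.grow_factor, spec.shrink_factor, 1.0)
    r_hi = spec.radius_range_um[1] * gmax ** ((T - 1) / 2.0)
    margin = spec.edge_margin_um
    if margin is None:
        margin = r_hi + 3.0 * spec.drift_sigma * math.sqrt(max(T - 1, 1)) + 2.0 * spec.pixel_size
        margin += (abs(spec.global_shift[0]) + abs(spec.global_shift[1])) * spec.pixel_size * (T - 1)
    lo = np.array([margin, margin])
    hi = np.array([w_um - margin, h_um - margin])
    if np.any(hi <= lo):
        raise PlacementError(
            f"image of {w_um:.0f}x{h_um:.0f} um leaves no interior after a {margin:.0f} um edge margin"
        )

    n_grow = int(round(spec.fraction_growing * n))
    grow_flags = np.zeros(n, dtype=bool)
    grow_flags[:n_grow] = True
    rng.shuffle(grow_flags)

    radii = rng.uniform(*spec.radius_range_um, size=n)
    # cluster members get similar radii and one shared growth factor
    # (contacting mesophyll protoplasts are alike in size, and contact alters
    # growth -- these cells are excluded from analysis regardless); a strongly
    # unequal pair would merge into a smooth teardrop that no
    # distance-transform split can separate
    for g in range(n_groups):
        members = np.arange(g * spec.cluster_size, (g + 1) * spec.cluster_size)
        base = radii[members].mean()
        radii[members] = base * np.linspace(0.9, 1.1, len(members))
        grow_flags[members] = grow_flags[members[0]]

    cells: list[SimulatedCell] = []
    traj = np.zeros((n, T, 2))
    placed_idx: list[int] = []

    # units: cluster groups first (rigid, shared drift), then isolated cells
    unit_members = [list(range(g * spec.cluster_size, (g + 1) * spec.cluster_size)) for g in range(n_groups)]
    unit_members += [[i] for i in range(n_clustered, n)]

    for u, members in enumerate(unit_members):
        group_id = u if len(members) > 1 else -1
        rel = (
            _sample_group(rng, spec, radii[members], group_id)
            if len(members) > 1
            else np.zeros((1, 2))
        )
        # contacting cells keep contact: member offsets scale with the summed
        # group radius so the relative overlap is constant over time
        factors = np.array(
            [spec.grow_factor if grow_flags[i] else spec.shrink_factor for i in members]
        )
        ts = np.arange(T)
        r_t = radii[members][:, None] * factors[:, None] ** (ts[None, :] / 2.0)  # (m, T)
        scale_t = r_t.sum(axis=0) / radii[members].sum()  # (T,)
        placed = False
        for _ in range(spec.max_place_tries):
            anchor = rng.uniform(lo, hi)
            drift = rng.normal(0.0, spec.drift_sigma, size=(T - 1, 2)) if spec.drift_sigma > 0 else np.zeros((T - 1, 2))
            walk = np.vstack([np.zeros(2), np.cumsum(drift, axis=0)])  # (T, 2)
            cand = (
                anchor[None, None, :]
                + rel[:, None, :] * scale_t[None, :, None]
                + walk[None, :, :]
            )  # (m, T, 2)
            if np.any(cand < lo) or np.any(cand > hi):
                continue
            if placed_idx:
                prev = traj[placed_idx]  # (p, T, 2)
                dmin = np.min(
                    np.linalg.norm(prev[:, None, :, :] - cand[None, :, :, :], axis=-1)
                )
                if dmin < spec.min_spacing:
                    continue
            for k, i in enumerate(members):
                traj[i] = cand[k]
                cells.append(
                    SimulatedCell(
                        cell_id=i + 1,
                        center0=tuple(cand[k, 0]),
                        radius0=float(radii[i]),
                        growth_factor=float(spec.grow_factor if grow_flags[i] else spec.shrink_factor),
                        drift_sigma=spec.drift_sigma,
                        intensity=spec.cell_intensity,
                        cluster_group=group_id,
                    )
                )
            placed_idx.extend(members)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place {len(members)} cell(s) at min_spacing={spec.min_spacing} um "
                f"within {w_um:.0f}x{h_um:.0f} um after {spec.max_place_tries} tries"
            )
    order = np.argsort([c.cell_id for c in cells])
    return [cells[i] for i in order], traj


def simulate_plate(spec: SimulationSpec) -> tuple[list[np.ndarray], GroundTruth]:
    """Simulate one well: one image per time point plus full ground truth.

    Cell areas evolve as ``area_t = area_0 * growth_factor**t``; centers
    drift by N(0, drift_sigma) per interval and the whole frame additionally
    translates by ``global_shift`` px per time point.  Identical specs
    (including seed) produce bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    cells, traj = _place_cells(spec, rng)

    rows = []
    images = []
    shift_um = np.array(spec.global_shift) * spec.pixel_size
    for t in range(spec.n_timepoints):
        img = np.full(spec.image_shape, spec.background, dtype=float)
        frame_shift = t * shift_um
        for cell in cells:
            i = cell.cell_id - 1
            pos = traj[i, t] + frame_shift
            r_t = cell.radius_at(t)
            _render_cell_inplace(img, tuple(pos), r_t, cell.intensity, spec.pixel_size)
            rows.append(
                (
                    cell.cell_id,
                    t,
                    pos[0],
                    pos[1],
                    r_t,
                    math.pi * r_t**2,
                    cell.growth_factor,
                    cell.cluster_group,
                    cell.cluster_group >= 0,
                )
            )
        if spec.stripe_amplitude:
            y = np.arange(spec.image_shape[0])
            img += spec.stripe_amplitude * np.sin(2.0 * math.pi * y / spec.stripe_period)[:, None]
        if spec.noise_sigma:
            img += rng.normal(0.0, spec.noise_sigma, size=spec.image_shape)
        images.append(np.clip(img, 0.0, 1.0))

    table = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    table = table.sort_values(["timepoint", "cell_id"]).reset_index(drop=True)
    return images, GroundTruth(table=table, spec=spec, cells=cells)


def write_plate(
    out_dir: str | Path,
    images: list[np.ndarray],
    well: str = "1B",
    truth: GroundTruth | None = None,
) -> list[Path]:
    """Write one grayscale TIFF per time point as ``<well>_TP<k>.tif`` (k 1-based)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, img in enumerate(images, start=1):
        p = out_dir / f"{well}_TP{k}.tif"
        tifffile.imwrite(p, (np.clip(img, 0.0, 1.0) * 65535).astype(np.uint16))
        paths.append(p)
    if truth is not None:
        truth.to_csv(out_dir / f"{well}_truth.csv")
    return paths


def with_seed(spec: SimulationSpec, seed: int) -> SimulationSpec:
    """Convenience: the same study conditions under a different RNG seed."""
    return replace(spec, seed=seed)
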