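"""Single-cell label maps from preprocessed frames.

A pluggable segmentation backend produces a binary mask (the reference
backend is a classical smoothing/Otsu/opening segmenter; a deep-learning
backend can be attached under the same contract).  Post-processing follows
the single-cell selection procedure: fill holes, split touching objects by
watershed on the distance transform, remove objects that split into two or
more substantial fragments (contacting-cell clusters whose single-cell
identity is ambiguous), drop frame-truncated objects, and measure region
features (centroid, area, circularity).

Conventions: 8-connected foreground, 4-connected background (hole
detection); perimeter is the pixel-edge boundary length, and circularity
4*pi*A/P^2 is capped at 1.0.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import gaussian, threshold_otsu, threshold_triangle
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "RECORD_COLUMNS",
    "segment_reference",
    "attach_backend",
    "get_backend",
    "run_backend",
    "fill_holes",
    "watershed_split",
    "filter_clusters",
    "exclude_border",
    "measure_regions",
    "relabel_dense",
]

#: columns of the per-frame cell-record table
RECORD_COLUMNS = [
    "well",
    "timepoint",
    "label",
    "cx_px",
    "cy_px",
    "cx_um",
    "cy_um",
    "area_px",
    "area_um2",
    "circularity",
    "touches_border",
]

Backend = Callable[[np.ndarray], np.ndarray]
_BACKENDS: dict[str, Backend] = {}


def segment_reference(
    image: np.ndarray,
    sigma: float = 1.5,
    polarity: str = "bright",
    opening_radius: int = 2,
    min_cell_area: int = 50,
    max_foreground_fraction: float = 0.45,
) -> np.ndarray:
    """Classical reference segmenter: smooth, global threshold, opening, area filter.

    The global threshold is chosen between Otsu's and the triangle
    criterion as whichever marks the smaller foreground fraction: Otsu is
    accurate when cells occupy a few percent of the frame but collapses
    into the background mode on very sparse frames, where the triangle
    rule (built for strongly skewed histograms) stays in the upper tail.
    Immobilized cells never cover close to half a well, so if the better
    candidate still marks more than ``max_foreground_fraction`` of the
    frame the histogram is unimodal (a blank or noise-only frame) and an
    empty mask is returned.  ``polarity`` selects whether cells are
    brighter or darker than the background.  The result is deterministic
    for fixed input.
    """
    img = np.asarray(image, dtype=float)
    if float(img.max() - img.min()) < 1e-9:
        return np.zeros(img.shape, dtype=bool)
    smooth = gaussian(img, sigma=sigma, preserve_range=True) if sigma > 0 else img
    if polarity == "bright":
        candidates = (smooth > t for t in (threshold_otsu(smooth), threshold_triangle(smooth)))
    elif polarity == "dark":
        candidates = (smooth < t for t in (threshold_otsu(smooth), threshold_triangle(smooth)))
    else:
        raise ValueError("polarity must be 'bright' or 'dark'")
    mask = min(candidates, key=lambda m: m.sum())
    if mask.mean() > max_foreground_fraction:
        return np.zeros(img.shape, dtype=bool)
    if opening_radius > 0:
        mask = ndi.binary_opening(mask, structure=morphology.disk(opening_radius))
    if min_cell_area > 0:
        lab = cc_label(mask, connectivity=2)
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes < min_cell_area)
        mask = mask & ~np.isin(lab, small[small > 0])
    return mask


def attach_backend(name: str, fn: Backend) -> None:
    """Register a segmentation backend: callable RasterImage -> BinaryMask."""
    if not callable(fn):
        raise TypeError("backend must be callable")
    _BACKENDS[name] = fn


def get_backend(name: str) -> Backend:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise KeyError(f"no segmentation backend named {name!r}; registered: {sorted(_BACKENDS)}")


def run_backend(name: str, image: np.ndarray) -> np.ndarray:
    """Run a registered backend and validate its output contract."""
    mask = get_backend(name)(image)
    mask = np.asarray(mask)
    if mask.shape != np.asarray(image).shape:
        raise ValueError(
            f"backend {name!r} returned shape {mask.shape}, expected {np.asarray(image).shape}"
        )
    if mask.dtype != bool:
        mask = mask.astype(bool)
    return mask


attach_backend("reference", segment_reference)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not connected to the frame border.

    Foreground never shrinks; holes are detected with 4-connectivity.
    """
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def _merge_close_seeds(markers: np.ndarray, min_sep: float) -> np.ndarray:
    """Union seed labels whose centroids are closer than min_sep pixels."""
    props = regionprops(markers)
    if len(props) < 2 or min_sep <= 0:
        return markers
    cents = np.array([p.centroid for p in props])
    labels = np.array([p.label for p in props])
    parent = {int(l): int(l) for l in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=-1)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if d[i, j] < min_sep:
                parent[find(int(labels[i]))] = find(int(labels[j]))
    lut = np.zeros(markers.max() + 1, dtype=markers.dtype)
    for l in labels:
        lut[l] = find(int(l))
    return lut[markers]


def watershed_split(
    mask: np.ndarray,
    min_seed_sep: float = 5.0,
    h_depth: float = 0.5,
) -> np.ndarray:
    """Split touching objects by watershed on the negative distance transform.

    Seeds are the h-maxima (depth ``h_depth`` px) of the Euclidean distance
    map; seeds closer than ``min_seed_sep`` px are merged so boundary
    roughness does not oversplit single convex cells.  Every foreground
    pixel is assigned to exactly one fragment.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    peaks = morphology.h_maxima(dist, h_depth)
    markers, _ = ndi.label(peaks, structure=np.ones((3, 3), dtype=int))
    markers = _merge_close_seeds(markers, min_seed_sep)
    labels = watershed(-dist, markers=markers, mask=mask)
    return relabel_dense(labels.astype(np.int32))


def filter_clusters(
    original: np.ndarray,
    split: np.ndarray,
    min_fragment_area: int = 20,
) -> tuple[np.ndarray, list[int]]:
    """Remove original labels that watershed splits into >= 2 substantial fragments.

    Mirrors the speckle-inspection step: the watershed fragments inside
    each originally segmented object are counted, ignoring fragments whose
    overlap is below ``min_fragment_area`` px (watershed slivers); objects
    with two or more substantial fragments are contacting-cell clusters and
    are removed.  Retained labels are relabeled densely; the removed
    original labels are returned.
    """
    original = np.asarray(original)
    split = np.asarray(split)
    if original.shape != split.shape:
        raise ValueError("original and split label maps must share a shape")
    if np.any((split > 0) & (original == 0)):
        raise ValueError("split foreground extends outside the original foreground")

    fg = (original > 0) & (split > 0)  # ridge pixels (split == 0) are tolerated
    if not fg.any():
        return np.zeros(original.shape, dtype=np.int32), []
    n_split = int(split.max())
    keys = original[fg].astype(np.int64) * (n_split + 1) + split[fg].astype(np.int64)
    uniq, counts = np.unique(keys, return_counts=True)
    orig_of_pair = uniq // (n_split + 1)
    substantial = counts >= min_fragment_area
    frag_counts = np.bincount(orig_of_pair[substantial].astype(int), minlength=int(original.max()) + 1)

    removed = [int(l) for l in np.unique(original[original > 0]) if frag_counts[l] >= 2]
    keep = np.isin(original, removed, invert=True) & (original > 0)
    kept_map = np.where(keep, original, 0)
    return relabel_dense(kept_map.astype(np.int32)), removed


def exclude_border(labels: np.ndarray) -> np.ndarray:
    """Remove labels touching the first/last row or column; relabel densely."""
    labels = np.asarray(labels)
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border = border[border > 0]
    if border.size == 0:
        return relabel_dense(labels.astype(np.int32))
    out = np.where(np.isin(labels, border), 0, labels)
    return relabel_dense(out.astype(np.int32))


def relabel_dense(labels: np.ndarray) -> np.ndarray:
    """Map positive labels onto 1..N preserving order; 0 stays background."""
    vals = np.unique(labels)
    vals = vals[vals > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    for new, old in enumerate(vals, start=1):
        lut[old] = new
    return lut[labels] if labels.size else labels.astype(np.int32)


def _edge_perimeters(labels: np.ndarray) -> np.ndarray:
    """Pixel-edge boundary length per label (index = label)."""
    nmax = int(labels.max())
    per = np.zeros(nmax + 1, dtype=np.int64)
    padded = np.pad(labels, 1, constant_values=0)
    core = padded[1:-1, 1:-1]
    for nb in (padded[:-2, 1:-1], padded[2:, 1:-1], padded[1:-1, :-2], padded[1:-1, 2:]):
        exposed = (core > 0) & (core != nb)
        per += np.bincount(core[exposed], minlength=nmax + 1)
    return per


def measure_regions(
    labels: np.ndarray,
    pixel_size: float = 1.0,
    well: str = "",
    timepoint: int = 0,
) -> pd.DataFrame:
    """Measure centroid, area and circularity for every labeled region.

    centroid = mean of member pixel coordinates; area is the exact pixel
    count (um^2 via pixel_size^2); perimeter is the pixel-edge boundary
    length of the region, and circularity = min(1, 4*pi*A/P^2).
    """
    labels = np.asarray(labels)
    perims = _edge_perimeters(labels)
    border_labels = set(
        np.unique(np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])).tolist()
    )
    rows = []
    for p in regionprops(labels):
        cy, cx = p.centroid
        area = int(p.area)
        perim = int(perims[p.label])
        circ = min(1.0, 4.0 * math.pi * area / perim**2) if perim > 0 else 1.0
        rows.append(
            (
                well,
                timepoint,
                int(p.label),
                cx,
                cy,
                cx * pixel_size,
                cy * pixel_size,
                area,
                area * pixel_size**2,
                circ,
                p.label in border_labels,
            )
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
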