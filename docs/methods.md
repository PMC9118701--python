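# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `protrack`.  It is written for a reader who wants to
know *why* the pipeline behaves as it does, not just what it computes.

## The measurement model

A protoplast is wall-free and near-spherical for roughly the first 48 h
after isolation, so its projected bright-field area `A` is a monotone
proxy for cell volume; turgor-driven swelling or shrinkage appears as an
area change.  The pipeline restricts analysis to the pre-division window
(the first few days after immobilization, DAI0–DAI3): once divisions
start, cell plates and regenerated walls decouple projected area from
single-cell volume, and dividing aggregates (microcalli) are instead
counted by a separate object-size criterion.

All per-cell quantities are ratios of areas of the *same* physical cell
at two times, so they are invariant to the pixel calibration and to any
uniform segmentation bias; this is why the pipeline tracks lineages
rather than comparing population snapshots.

## Preprocessing

Frames of one well are aligned to the first time point by the argmax of
normalized cross-correlation over integer shifts within a ±20 px window
(translation only — the plate is re-positioned between recordings, never
rotated).  Constant frames cannot be aligned and are flagged, not failed.
Vacated margins after translation are filled with the frame median as a
background estimate.

Each frame is then cropped into a 3×3 grid (the last row/column absorbs
any remainder, so tile sizes differ by ≤ 2 px and re-stitching is
bit-exact), and per tile:

1. **Local contrast normalization** —
   `out = mid + (in − µ_r) · target_σ / max(σ_r, ε)` with box statistics
   over a (2·90 + 1)² window, reflective padding, `target_σ = stds·range/6`
   and a small floor `ε = 10⁻⁴`.  This flattens illumination gradients and
   tile shading at scales above the box radius.
2. **Percentile stretch** — the 0.4th and 99.6th percentiles (0.8%
   saturated, split equally between tails) map linearly to the intensity
   range.  The bounds are computed once per *frame* on the stitched
   local-contrast output and applied identically to every tile: per-tile
   bounds would send a tile that happens to contain no cells to a flat
   mid-grey plateau, which downstream thresholding sees as one giant
   object.  A constant image passes through unchanged.
3. **Bandpass** — Gaussian frequency weights
   `exp(−ln2·(f·s)²)·(1 − exp(−ln2·(f·L)²))` with 50% amplitude gain at
   the cutoff structure sizes `s = 3` px and `L = 100` px, preserving the
   DC term (mean) and clipping to the input range.  Stripe suppression
   removes a Gaussian *wedge* around the stripe axis in frequency space
   whose angular half-width is 5% of a quadrant — a direction tolerance.
   Pure stripes sit exactly on the axis and lose ≥ 99% of their energy,
   while a compact object loses only the small angular slice of its
   spectrum inside the wedge.  (A fixed-width frequency *band* of the
   same nominal tolerance would span the entire x-spectrum of a 30–40 px
   cell and hollow it out; the wedge form is what keeps the parameter
   meaningful on tile-sized spectra.)

No preprocessing stage moves an isolated cell centroid by more than 1 px
on clean synthetic frames (asserted in the test suite).

## Segmentation and single-cell selection

The segmentation backend is pluggable: any callable mapping a frame to a
same-shaped boolean mask can be registered (`attach_backend`), which is
where a learned segmenter would plug in.  The built-in reference backend
is deliberately classical and fully deterministic:

- Gaussian smoothing, σ = 1.5 px — enough to suppress residual pixel
  noise without fusing the necks between touching cells.
- A global threshold chosen between **Otsu** and the **triangle**
  criterion, keeping whichever marks the smaller foreground fraction.
  Otsu is accurate when cells cover a few percent of the frame but, on
  very sparse frames whose background texture was amplified by the local
  contrast step, collapses into the background mode and segments half the
  well; the triangle rule, designed for strongly skewed histograms, stays
  in the upper tail there.  If even the better candidate marks more than
  45% of the frame as foreground, the histogram is unimodal — a blank or
  noise-only frame — and the frame is declared cell-free (immobilized
  monolayers never approach half coverage; the synthetic wells top out
  near 35%).
- Morphological opening (disk radius 2 px) and removal of objects below
  `min_cell_area = 50` px (the smallest plausible protoplast at 1 µm/px,
  ~8 µm diameter, covers ~50 px; configurable for other calibrations).

Post-processing: holes are filled (4-connected background not reaching
the border), objects are labeled 8-connected, and the mask is watershed-
split on the negative Euclidean distance transform.  Watershed seeds are
the h-maxima of the distance map with depth 0.5 px, merged when closer
than 5 px.  The distance transform of a convex object is unimodal, so the
shallow depth does not oversplit single cells (verified: zero false
splits across 1200 isolated simulated cells), while it still finds the
saddle between marginally overlapping neighbours.

**Cluster filtering** then compares the original label map with the
watershed map: an original object containing ≥ 2 watershed fragments of
at least `min_fragment_area = 20` px each is a clump of touching cells —
its members' areas and identities are unreliable, and contact itself
changes growth — so the object is removed from tracking.  The fragment
area floor guards against boundary slivers flagging a single cell.
Objects touching the frame border are removed as well (truncated area).
Every frame's ledger satisfies
`segmented = retained + cluster-removed + border-removed` exactly.

Region features use the exact pixel count as area, the mean of member
pixel coordinates as centroid, and the **pixel-edge boundary length** as
perimeter.  Circularity `min(1, 4πA/P²)` therefore has closed-form test
values (a filled square gives π/4) but saturates near π²/16 ≈ 0.62 for
digital disks, whose staircase boundary has length 2(w+h) ≈ 8r; this
convention is simple and exactly testable, and all uses of circularity in
the pipeline are comparative.

## Tracking

Matching between consecutive days minimizes centroid distance
`d_ij` in µm under a 27 µm maximum shift.  Candidate pairs are accepted
greedily in ascending distance with a one-to-one constraint and a
deterministic tie-break on labels.  In the immobilized-plate regime —
neighbour spacing well above twice the shift threshold — every cell has
at most one candidate partner, so greedy matching provably equals the
minimum-total-distance assignment; the test suite asserts this against an
exhaustive oracle (n ≤ 8) and an optimal-assignment oracle (n ≤ 50) on
200 random instances.  Matches are chained into lineages anchored at the
first recording (DAI0); a lineage broken at interval k keeps
`complete_through = k` and is excluded from any statistic that needs a
later day.  Direction of matching does not matter (distances are
symmetric); "retrograde" tracking affects bookkeeping only.

## Statistics

- **Growth rate** `g = A_k / A_0` per lineage; `g` computed from µm² and
  from raw pixel counts agree to machine precision.
- **Response ratio** `n = n_{g>1} / n_{g<1}` with strict inequalities;
  lineages with `g` exactly 1 are reported separately and excluded from
  both counts.  `n` is undefined (None) when nothing shrank.
- **Interval change** `(A_{k+1} − A_k)/A_k` per consecutive tracked pair,
  with well/replicate grouping columns carried through for replicate
  means.
- **Histograms** use half-open fixed-width bins (default 100 µm², about
  the granularity at which the bimodal grower/shrinker structure is
  visible); counts are always conserved.
- **Equivalent radius** `√(A/π)`: the radius of the disk with area `A`,
  the numeric convention used for summarizing population mean areas
  (850 µm² ↔ 16.45 µm).
- **Proliferation rate**: objects larger than 4000 px at a late day are
  proliferating microcalli;
  `rate = (n_large_late − n_large_early)/(n_cells_early − n_large_early)`
  subtracts the already-large background objects from both the numerator
  and the reference count (reading "normalized to cell number after
  subtracting background" as excluding background objects from both);
  a negative numerator clamps to 0 with a warning.  The threshold is
  exposed in pixels because it is defined in pixels.

## The synthetic wells

`imagesim` renders what the analysis needs to be true of real data and
nothing more: quasi-circular cells as anti-aliased disks (radii uniform
in 7.5–20 µm, i.e. the 15–40 µm diameters of mesophyll protoplasts),
bright on a dark background, with additive Gaussian noise, optional
horizontal stripe artifacts, a global per-frame translation (what the
alignment stage corrects), and per-cell Gaussian positional jitter
(σ = 5 µm per interval — the recordings show only slight displacements,
and this sits safely below the 27 µm matching threshold).  Areas evolve
as `A_t = A_0·g^t` with `g = 1.2` for a configurable growing fraction
(default 40%) and `g = 0.9` otherwise.  Non-cluster cells keep a 60 µm
hard-core spacing at every time point (rejection sampling over whole
trajectories).  Cluster groups are placed with centers at 80% of the
summed radii, share one drift trajectory and one growth factor, draw
similar radii (group mean ± 10%), and their offsets scale with the group
radius so contact persists — contacting protoplasts in real wells are
alike in size and stay in contact, and these cells are excluded from
analysis regardless.

The default plate holds 300 cells on a 1700×1700 px frame at 1 µm/px.
Real wells hold ~8000 protoplasts; the scaled-down density keeps
rejection sampling and the full-plate tests cheap while preserving the
geometry that matters for tracking (spacing ≫ shift threshold).  Fixed
seeds make every simulation bit-reproducible.

What the simulator does **not** emulate — and what passing tests
therefore do not show about real data: optics (PSF, defocus), chloroplast
and cytoplasm texture, dark cell rims of real bright-field protoplasts,
cell division, death and lysis, and well-scale illumination fields beyond
a linear gradient.  Segmentation accuracy on real micrographs is a
property of the attached backend, not of this pipeline; the tests
demonstrate that *given* faithful masks (or images the reference
segmenter can handle), tracking and statistics recover the truth.

## Known limitations

- Classical distance-transform splitting cannot separate a touching pair
  once blur erases the neck between them: after a shrink interval the
  smallest simulated pairs (radii ≈ 8 px, overlap ≈ 3 px) occasionally
  fuse into a single smooth blob with one distance maximum, and cluster
  recall on random plates dips to ~0.92 for some seeds (precision stays
  1.0).  A learned segmenter that separates the cells before watershed
  removes this failure mode.
- A pair of cells of very different radii in deep overlap renders as a
  smooth teardrop that no watershed parameterization can split without
  oversplitting single cells; the simulator avoids generating this
  unidentifiable geometry.
- Alignment is integer-pixel and translation-only by design; rotation or
  scale drift of the plate is out of scope.
- Greedy matching equals optimal assignment only in the sparse regime;
  at densities where neighbours come within twice the shift threshold,
  identity switches become possible (the 60 µm default spacing keeps the
  probability of even one switch per 300-cell plate negligible).
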