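"""Independent matching oracles and instance generators for tracking tests.

The oracles maximize matched-pair count and, among maximum matchings,
minimize total distance -- by exhaustive recursion for small frames and by
optimal assignment (Hungarian with a big-M penalty) for larger ones.  They
share no code with the greedy matcher under test.
"""

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from protrack.segment import RECORD_COLUMNS


def make_records(points_um, well="1B", timepoint=0):
    """Minimal cell-record table from an (n, 2) array of (x, y) um centroids."""
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    df = pd.DataFrame(
        {
            "well": well,
            "timepoint": timepoint,
            "label": np.arange(1, len(pts) + 1),
            "cx_px": pts[:, 0],
            "cy_px": pts[:, 1],
            "cx_um": pts[:, 0],
            "cy_um": pts[:, 1],
            "area_px": 100,
            "area_um2": 100.0,
            "circularity": 1.0,
            "touches_border": False,
        }
    )
    return df[RECORD_COLUMNS]


def brute_force_match(p1, p2, threshold):
    """Exhaustive search over all one-to-one matchings (n <= 8 per side)."""
    p1 = np.asarray(p1, float).reshape(-1, 2)
    p2 = np.asarray(p2, float).reshape(-1, 2)
    d = cdist(p1, p2) if len(p1) and len(p2) else np.empty((len(p1), len(p2)))
    best = {"key": None, "pairs": set()}

    def rec(i, used2, pairs, total):
        if i == len(p1):
            key = (-len(pairs), total)
            if best["key"] is None or key < best["key"]:
                best["key"] = key
                best["pairs"] = set(pairs)
            return
        rec(i + 1, used2, pairs, total)  # leave i unmatched
        for j in range(len(p2)):
            if j not in used2 and d[i, j] <= threshold:
                rec(i + 1, used2 | {j}, pairs + [(i, j)], total + d[i, j])

    rec(0, frozenset(), [], 0.0)
    total = sum(d[i, j] for i, j in best["pairs"])
    return best["pairs"], total


def assignment_match(p1, p2, threshold):
    """Optimal one-to-one assignment with a big-M penalty for over-threshold pairs."""
    p1 = np.asarray(p1, float).reshape(-1, 2)
    p2 = np.asarray(p2, float).reshape(-1, 2)
    if len(p1) == 0 or len(p2) == 0:
        return set(), 0.0
    d = cdist(p1, p2)
    big = d.sum() + threshold * (len(p1) + len(p2)) + 1.0
    cost = np.where(d <= threshold, d, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = {(int(i), int(j)) for i, j in zip(rows, cols) if d[i, j] <= threshold}
    return pairs, sum(d[i, j] for i, j in pairs)


def random_instance(rng, n_max, threshold, box=1500.0):
    """Frame pair with pairwise spacing >= 2x threshold inside each frame.

    Earlier-frame points are placed by rejection sampling at >= 2.05x
    threshold spacing; survivors move by at most 0.45x threshold (so every
    candidate pair is unique), ~10% of cells disappear, and a few new cells
    appear far from everything.  In this regime greedy matching, exhaustive
    search and optimal assignment provably coincide.
    """
    spacing = 2.05 * threshold
    n = int(rng.integers(2, n_max + 1))
    pts = []
    tries = 0
    while len(pts) < n and tries < 4000:
        tries += 1
        cand = rng.uniform(0, box, 2)
        if all(np.linalg.norm(cand - p) >= spacing for p in pts):
            pts.append(cand)
    p1 = np.array(pts)
    keep = rng.random(len(p1)) > 0.1
    moved = []
    expected = {}
    for i in np.flatnonzero(keep):
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(0, 0.45 * threshold)
        moved.append(p1[i] + r * np.array([np.cos(ang), np.sin(ang)]))
        expected[i] = len(moved) - 1
    p2 = list(moved)
    for _ in range(int(rng.integers(0, 3))):
        for _ in range(200):
            cand = rng.uniform(0, box, 2)
            others = np.vstack([p1] + p2) if p2 else p1
            if np.min(np.linalg.norm(others - cand, axis=1)) >= spacing:
                p2.append(cand)
                break
    return p1, np.array(p2), expected
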