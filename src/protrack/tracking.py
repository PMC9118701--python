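"""Retrograde single-cell tracking by Euclidean centroid distance.

A cell at one time point is identified at the next by the Euclidean
distance between centroids, d_ij = sqrt((x_i - x_j)^2 + (y_i - y_j)^2) in
um, accepted only below a maximum-shift threshold (default 27 um).
Candidate pairs are taken greedily in ascending distance under a
one-to-one constraint, which equals the minimum-total-distance assignment
whenever nearest neighbours are mutual -- the regime the immobilized-cell
geometry guarantees.  Matches over consecutive day pairs are chained into
lineages anchored at DAI0; all growth statistics consume these lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["MatchSet", "Lineage", "match_cells", "build_lineages", "lineage_table"]

DEFAULT_MAX_SHIFT_UM = 27.0


@dataclass
class MatchSet:
    """One-to-one matches between an earlier and a later time point.

    ``pairs`` holds (label_t1, label_t2, d_um) with every d_um <= threshold;
    no label appears in two pairs.
    """

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    unmatched_t1: list[int] = field(default_factory=list)
    unmatched_t2: list[int] = field(default_factory=list)
    threshold_um: float = DEFAULT_MAX_SHIFT_UM

    def as_dict(self) -> dict[int, int]:
        return {i: j for i, j, _ in self.pairs}


@dataclass
class Lineage:
    """DAI0-anchored chain of one cell's records across time points."""

    lineage_id: int
    labels: dict[int, int]  # timepoint -> label
    complete_through: int  # last DAI with a match

    def __len__(self) -> int:
        return len(self.labels)


def match_cells(
    records_t1: pd.DataFrame,
    records_t2: pd.DataFrame,
    max_shift_um: float = DEFAULT_MAX_SHIFT_UM,
) -> MatchSet:
    """Greedy ascending-distance one-to-one matching under the shift threshold.

    Exact distance ties break on the smaller (label_t1, label_t2) pair, so
    the result is deterministic.  Empty inputs yield an empty MatchSet;
    mixing records from different wells is an error.
    """
    ms = MatchSet(threshold_um=float(max_shift_um))
    labels1 = records_t1["label"].to_numpy(dtype=int) if len(records_t1) else np.empty(0, dtype=int)
    labels2 = records_t2["label"].to_numpy(dtype=int) if len(records_t2) else np.empty(0, dtype=int)
    if len(records_t1) == 0 or len(records_t2) == 0:
        ms.unmatched_t1 = sorted(labels1.tolist())
        ms.unmatched_t2 = sorted(labels2.tolist())
        return ms
    wells = set(records_t1["well"]) | set(records_t2["well"])
    if len(wells) > 1:
        raise ValueError(f"records mix wells: {sorted(wells)}")

    p1 = records_t1[["cx_um", "cy_um"]].to_numpy(dtype=float)
    p2 = records_t2[["cx_um", "cy_um"]].to_numpy(dtype=float)
    d = cdist(p1, p2)
    ii, jj = np.nonzero(d <= max_shift_um)
    candidates = sorted(
        zip(d[ii, jj], labels1[ii].tolist(), labels2[jj].tolist())
    )
    used1: set[int] = set()
    used2: set[int] = set()
    for dist, l1, l2 in candidates:
        if l1 in used1 or l2 in used2:
            continue
        ms.pairs.append((int(l1), int(l2), float(dist)))
        used1.add(l1)
        used2.add(l2)
    ms.unmatched_t1 = sorted(set(labels1.tolist()) - used1)
    ms.unmatched_t2 = sorted(set(labels2.tolist()) - used2)
    return ms


def build_lineages(matchsets: list[MatchSet], labels_t0: list[int]) -> list[Lineage]:
    """Chain per-interval matches transitively from the DAI0 anchor.

    ``matchsets[k]`` must cover the (DAI k, DAI k+1) interval.  A lineage's
    ``complete_through`` is the last DAI reached; lineages feeding a
    DAI0 -> DAIk statistic must have complete_through >= k.
    """
    maps = [ms.as_dict() for ms in matchsets]
    for m in maps:
        if len(set(m.values())) != len(m):
            raise ValueError("inconsistent MatchSet: a later-frame cell appears in two chains")
    lineages = []
    for lid, l0 in enumerate(sorted(labels_t0), start=1):
        chain = {0: int(l0)}
        cur = int(l0)
        for k, m in enumerate(maps):
            if cur not in m:
                break
            cur = m[cur]
            chain[k + 1] = cur
        lineages.append(Lineage(lineage_id=lid, labels=chain, complete_through=max(chain)))
    return lineages


def lineage_table(lineages: list[Lineage], records_by_tp: list[pd.DataFrame]) -> pd.DataFrame:
    """Flatten lineages into one row per (lineage, time point) with features.

    Columns: lineage_id, complete_through, well, timepoint, label, cx_um,
    cy_um, area_px, area_um2, circularity.
    """
    indexed = [df.set_index("label") for df in records_by_tp]
    rows = []
    for lin in lineages:
        for t, lab in sorted(lin.labels.items()):
            rec = indexed[t].loc[lab]
            rows.append(
                (
                    lin.lineage_id,
                    lin.complete_through,
                    rec["well"],
                    t,
                    lab,
                    rec["cx_um"],
                    rec["cy_um"],
                    rec["area_px"],
                    rec["area_um2"],
                    rec["circularity"],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lineage_id",
            "complete_through",
            "well",
            "timepoint",
            "label",
            "cx_um",
            "cy_um",
            "area_px",
            "area_um2",
            "circularity",
        ],
    )
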