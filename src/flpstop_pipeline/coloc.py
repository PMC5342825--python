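"""3D spot colocalization: count double-labeled cells from point coordinates.

Cell centres for each channel (e.g., GFP-positive and tdTomato-positive cell
bodies) are supplied as 3D coordinates in µm.  Two spots colocalize when
their distance is strictly below a threshold (3.5 µm for medulla cell types,
2.5 µm for the more tightly packed T4 cells).  Matching is one-to-one and
distance-optimal: it pairs as many spots as possible (maximum-cardinality
bipartite matching over the sub-threshold pairs) and, among such matchings,
minimizes the total matched distance.  One-to-one matching prevents a single
spot in channel B from validating many spots in channel A; a simpler greedy
nearest-pair strategy can drop pairs a better arrangement would keep, which
is why the optimal matching is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree


@dataclass
class SpotSet:
    """A set of 3D spot coordinates (µm) from one channel."""

    points: np.ndarray
    channel: str = ""
    specimen_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of µm coordinates")
        if not np.all(np.isfinite(pts)):
            raise ValueError("spot coordinates must be finite")
        if len(pts) > 1 and cKDTree(pts).query_pairs(1e-9):
            raise ValueError("duplicate points (within 1e-9 µm) in spot set")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ColocResult:
    threshold_um: float
    pairs: list[tuple[int, int, float]]  # (a_index, b_index, distance_um)
    n_a: int
    n_b: int

    @property
    def percent_a_colocalized(self) -> float:
        return 100.0 * len(self.pairs) / self.n_a


def colocalize(
    a: SpotSet,
    b: SpotSet,
    threshold_um: float,
    one_to_one: bool = True,
) -> ColocResult:
    """Match spots in ``a`` to spots in ``b`` within a distance threshold.

    Candidate pairs are all (i, j) with distance strictly less than
    ``threshold_um``.  With ``one_to_one`` (default, recommended) the result
    is the maximum-cardinality matching over candidate pairs that minimizes
    the total matched distance (solved as a linear assignment with forbidden
    pairs priced out), so each spot is used at most once and no alternative
    arrangement could pair more spots.  With ``one_to_one=False`` every
    a-spot with any b-spot within the threshold counts (a
    sensitivity-analysis mode; can exceed the one-to-one count).
    """
    if threshold_um <= 0:
        raise ValueError("threshold_um must be positive")
    if len(a) == 0:
        raise ValueError("spot set a must be nonempty")
    if len(b) == 0:
        return ColocResult(threshold_um, [], len(a), 0)

    tree = cKDTree(b.points)
    if not one_to_one:
        d, j = tree.query(a.points, k=1)
        pairs = [(i, int(j[i]), float(d[i])) for i in range(len(a)) if d[i] < threshold_um]
        return ColocResult(threshold_um, pairs, len(a), len(b))

    # sparse candidate set; restrict the assignment to spots with any
    # sub-threshold partner to keep the cost matrix small
    neighbors = tree.query_ball_point(a.points, threshold_um)
    a_idx = [i for i, nb in enumerate(neighbors) if nb]
    b_idx = sorted({j for nb in neighbors for j in nb})
    if not a_idx:
        return ColocResult(threshold_um, [], len(a), len(b))
    b_pos = {j: col for col, j in enumerate(b_idx)}
    # forbidden pairs cost more than any full matching of allowed pairs,
    # so the solver maximizes the number of allowed pairs first
    big = (min(len(a_idx), len(b_idx)) + 1) * threshold_um
    cost = np.full((len(a_idx), len(b_idx)), big)
    for row, i in enumerate(a_idx):
        for j in neighbors[i]:
            d = float(np.linalg.norm(a.points[i] - b.points[j]))
            if d < threshold_um:
                cost[row, b_pos[j]] = d
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (a_idx[r], b_idx[c], float(cost[r, c]))
        for r, c in zip(rows, cols)
        if cost[r, c] < threshold_um
    ]
    pairs.sort(key=lambda p: (p[2], p[0], p[1]))
    return ColocResult(threshold_um, pairs, len(a), len(b))


def percent_double_labeled(specimen_percentages: Sequence[float]) -> dict:
    """Summarize per-specimen colocalization percentages.

    Mean and SEM are computed across specimen-level percentages (each
    individually scored visual system is one observation), not across pooled
    cells.  With a single specimen the SEM is undefined and reported as 0
    with ``sem_defined = False``.
    """
    vals = np.asarray(list(specimen_percentages), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one specimen")
    mean = float(vals.mean())
    if vals.size == 1:
        return {"mean": mean, "sem": 0.0, "sem_defined": False, "values": vals.tolist()}
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size))
    return {"mean": mean, "sem": sem, "sem_defined": True, "values": vals.tolist()}
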