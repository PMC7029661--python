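"""ROI grouping by k-medoids, the partition consumed by group penalties.

Group-penalized hyperedge construction needs a predefined, non-overlapping
partition of the ROIs.  Pairwise similarity between regions is the Pearson
correlation of their time series; the clustering distance is 1 - r.  Medoid
seeding follows the k-means++ idea with selection probability proportional to
the distance to the nearest already-chosen seed (distance itself, not its
square), and the clustering is restarted from several seedings, keeping the
lowest-cost result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import SubjectTimeSeries

__all__ = [
    "GroupingResult",
    "correlation_distance",
    "kmedoids_pp_seeds",
    "kmedoids",
    "cluster_rois",
]


@dataclass
class GroupingResult:
    """Partition of ROIs into k non-empty groups around medoid ROIs."""

    k: int
    assignment: np.ndarray  # ROI index -> group index in [0, k)
    medoids: np.ndarray  # group index -> ROI index
    cost: float

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.medoids = np.asarray(self.medoids, dtype=int)
        if self.medoids.shape[0] != self.k:
            raise ValueError("need exactly k medoids")
        counts = np.bincount(self.assignment, minlength=self.k)
        if np.any(counts == 0):
            raise ValueError("every group must contain at least one ROI")
        if np.any(self.assignment[self.medoids] != np.arange(self.k)):
            raise ValueError("each medoid must belong to its own group")

    def groups(self) -> list[np.ndarray]:
        """Column-index arrays per group, as consumed by PenaltySpec."""
        return [np.flatnonzero(self.assignment == g) for g in range(self.k)]

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            {"roi_index": np.arange(self.assignment.size), "group_index": self.assignment}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "GroupingResult":
        df = pd.read_csv(path, sep="\t")
        assignment = df.sort_values("roi_index")["group_index"].to_numpy()
        k = int(assignment.max()) + 1
        # medoids are not stored; use the lowest ROI index per group
        medoids = np.array([int(np.flatnonzero(assignment == g)[0]) for g in range(k)])
        return cls(k=k, assignment=assignment, medoids=medoids, cost=np.nan)


def correlation_distance(data: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between ROI rows; symmetric, zero diagonal."""
    data = np.asarray(data, dtype=float)
    sd = data.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"ROI {bad} has zero variance")
    dist = 1.0 - np.corrcoef(data)
    np.fill_diagonal(dist, 0.0)
    return np.clip((dist + dist.T) / 2.0, 0.0, 2.0)


def kmedoids_pp_seeds(
    distances: np.ndarray, k: int, rng: int | np.random.Generator
) -> np.ndarray:
    """k distinct seed indices; after a uniform first pick, each next seed is
    drawn with probability proportional to its distance to the nearest seed."""
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seeds = [int(rng.integers(n))]
    while len(seeds) < k:
        nearest = distances[:, seeds].min(axis=1)
        nearest[seeds] = 0.0
        total = nearest.sum()
        if total <= 0:  # all remaining points coincide with a seed
            remaining = np.setdiff1d(np.arange(n), seeds)
            seeds.append(int(rng.choice(remaining)))
            continue
        seeds.append(int(rng.choice(n, p=nearest / total)))
    return np.array(seeds, dtype=int)


def _assign(distances: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Nearest-medoid assignment; ties go to the earliest medoid in the list,
    and a medoid always belongs to its own group."""
    assignment = np.argmin(distances[:, medoids], axis=1)
    assignment[medoids] = np.arange(medoids.size)
    return assignment


def kmedoids(
    distances: np.ndarray, seeds: Sequence[int], max_iterations: int = 100
) -> GroupingResult:
    """Alternate nearest-medoid assignment and per-group medoid update until a
    fixed point; cost (total distance to assigned medoid) never increases.
    Medoid-update ties are broken by the smallest ROI index."""
    distances = np.asarray(distances, dtype=float)
    medoids = np.asarray(seeds, dtype=int)
    if np.unique(medoids).size != medoids.size:
        raise ValueError("seeds must be distinct")
    k = medoids.size
    assignment = _assign(distances, medoids)
    for _ in range(max_iterations):
        new_medoids = medoids.copy()
        for g in range(k):
            members = np.flatnonzero(assignment == g)
            within = distances[np.ix_(members, members)].sum(axis=0)
            new_medoids[g] = members[int(np.argmin(within))]  # argmin: lowest index on ties
        new_assignment = _assign(distances, new_medoids)
        if np.array_equal(new_medoids, medoids) and np.array_equal(
            new_assignment, assignment
        ):
            break
        medoids, assignment = new_medoids, new_assignment
    cost = float(distances[np.arange(distances.shape[0]), medoids[assignment]].sum())
    return GroupingResult(k=k, assignment=assignment, medoids=medoids, cost=cost)


def cluster_rois(
    cohort: Sequence[SubjectTimeSeries] | np.ndarray,
    k: int,
    restarts: int = 10,
    rng_seed: int = 0,
) -> GroupingResult:
    """One shared ROI partition for a dataset.

    The ROI x ROI correlation is computed from the mean-centered subject
    series concatenated along time (one grouping for all subjects), then
    k-medoids is run from ``restarts`` independent seedings; the lowest-cost
    result wins, ties broken by the earliest restart.
    """
    if isinstance(cohort, np.ndarray):
        data = cohort
    else:
        data = np.concatenate(
            [s.data - s.data.mean(axis=1, keepdims=True) for s in cohort], axis=1
        )
    distances = correlation_distance(data)
    best: GroupingResult | None = None
    for r in range(restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=rng_seed, spawn_key=(r,))
        )
        seeds = kmedoids_pp_seeds(distances, k, rng)
        result = kmedoids(distances, seeds)
        if best is None or result.cost < best.cost:
            best = result
    assert best is not None
    return best
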