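"""Per-subject hypergraph construction from sparse regressions.

Every ROI in turn is the centroid of a sparse regression; the ROIs with
nonzero coefficients plus the centroid form one hyperedge.  Repeating this
over a multi-level grid of regularization ratios (default 0.1..0.9, nine
values) yields n_rois * n_ratios hyperedges per subject — 810 columns for the
default 90-ROI atlas — collected in a binary node x hyperedge incidence
matrix.  Degenerate singleton edges (all-zero solutions) and duplicate
columns are retained so the incidence shape is fixed across subjects and
feature columns align.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grouping import GroupingResult
from .solvers import (
    CoefficientVector,
    PenaltySpec,
    RegressionProblem,
    SolverConfig,
    solve_sparse_regression,
)
from .synthetic import SubjectTimeSeries

__all__ = [
    "LambdaGrid",
    "Hypergraph",
    "build_hyperedge",
    "build_hypernetwork",
    "node_degree",
    "edge_degree",
    "edge_degree_distribution",
]

DEFAULT_BINS: tuple[tuple[int, float], ...] = ((2, 7), (8, 13), (14, 19), (20, np.inf))


@dataclass(frozen=True)
class LambdaGrid:
    """Multi-level regularization grid.

    ``ratios`` drive the per-edge penalty (the single ratio of lasso/glasso,
    the l1 ratio of sglasso); ``fixed_group_ratio`` is sglasso's group-level
    ratio, held fixed across the grid (0.4 by default, the setting reported
    to classify best).
    """

    ratios: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    fixed_group_ratio: float = 0.4

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratios", tuple(float(r) for r in self.ratios))
        if not self.ratios:
            raise ValueError("ratios must be non-empty")
        if any(not 0.0 < r < 1.0 for r in self.ratios):
            raise ValueError("ratios must lie in (0, 1)")
        if any(b <= a for a, b in zip(self.ratios, self.ratios[1:])):
            raise ValueError("ratios must be strictly increasing")
        if not 0.0 < self.fixed_group_ratio < 1.0:
            raise ValueError("fixed_group_ratio must lie in (0, 1)")


@dataclass
class Hypergraph:
    """Binary incidence matrix (nodes x hyperedges) with per-edge metadata."""

    n_nodes: int
    incidence: np.ndarray
    edge_meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=np.uint8)
        if self.incidence.ndim != 2 or self.incidence.shape[0] != self.n_nodes:
            raise ValueError("incidence must be n_nodes x n_edges")
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValueError("incidence entries must be binary")
        if self.edge_meta and len(self.edge_meta) != self.n_edges:
            raise ValueError("edge_meta length must match edge count")

    @property
    def n_edges(self) -> int:
        return self.incidence.shape[1]

    def members(self, e: int) -> np.ndarray:
        return np.flatnonzero(self.incidence[:, e])

    def node_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=1).astype(int)

    def edge_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=0).astype(int)

    # ---- serialization -------------------------------------------------
    def to_incidence_tsv(self, path: str) -> None:
        np.savetxt(path, self.incidence, fmt="%d", delimiter="\t")

    @classmethod
    def from_incidence_tsv(cls, path: str) -> "Hypergraph":
        inc = np.loadtxt(path, delimiter="\t", dtype=int)
        inc = np.atleast_2d(inc)
        return cls(n_nodes=inc.shape[0], incidence=inc)

    def to_edgelist_tsv(self, path: str) -> None:
        """Sparse text format: edge_id, centroid, lambda_ratio, member list."""
        with open(path, "w") as fh:
            fh.write("edge_id\tcentroid\tlambda_ratio\tmembers\n")
            for e in range(self.n_edges):
                meta = self.edge_meta[e] if self.edge_meta else {}
                members = ",".join(str(v) for v in self.members(e))
                fh.write(
                    f"{e}\t{meta.get('centroid', '')}\t{meta.get('ratio', '')}\t{members}\n"
                )

    @classmethod
    def from_edgelist_tsv(cls, path: str, n_nodes: int) -> "Hypergraph":
        edges = []
        meta = []
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                edge_id, centroid, ratio, members = line.rstrip("\n").split("\t")
                nodes = [int(v) for v in members.split(",")] if members else []
                edges.append(nodes)
                meta.append(
                    {
                        "centroid": int(centroid) if centroid else None,
                        "ratio": float(ratio) if ratio else None,
                    }
                )
        inc = np.zeros((n_nodes, len(edges)), dtype=np.uint8)
        for e, nodes in enumerate(edges):
            inc[nodes, e] = 1
        return cls(n_nodes=n_nodes, incidence=inc, edge_meta=meta)


def build_hyperedge(coeffs: CoefficientVector, centroid: int) -> np.ndarray:
    """Hyperedge node set: the regression support plus the centroid itself."""
    return np.union1d(coeffs.support, [centroid]).astype(int)


def _penalty_for(method: str, ratio: float, grid: LambdaGrid, partition) -> PenaltySpec:
    groups = partition.groups() if isinstance(partition, GroupingResult) else partition
    if method == "lasso":
        return PenaltySpec(kind="lasso", ratio_l1=ratio)
    if method == "glasso":
        return PenaltySpec(kind="glasso", ratio_group=ratio, partition=groups)
    return PenaltySpec(
        kind="sglasso",
        ratio_l1=ratio,
        ratio_group=grid.fixed_group_ratio,
        partition=groups,
    )


def build_hypernetwork(
    subject: SubjectTimeSeries,
    method: str = "sglasso",
    grid: LambdaGrid | None = None,
    partition: GroupingResult | Sequence[np.ndarray] | None = None,
    solver_config: SolverConfig | None = None,
) -> Hypergraph:
    """One hypergraph per subject: a solve per (centroid ROI, grid ratio).

    Columns are ordered ROI-major then ratio ascending, so the incidence has
    exactly ``n_rois * len(grid.ratios)`` columns and every column contains
    its centroid.
    """
    grid = grid or LambdaGrid()
    if method not in ("lasso", "glasso", "sglasso"):
        raise ValueError(f"unknown method {method!r}")
    if method != "lasso" and partition is None:
        raise ValueError(f"{method} requires an ROI partition")
    n = subject.n_rois
    incidence = np.zeros((n, n * len(grid.ratios)), dtype=np.uint8)
    meta: list[dict] = []
    col = 0
    for m in range(n):
        problem = RegressionProblem.from_timeseries(subject.data, m)
        for ratio in grid.ratios:
            spec = _penalty_for(method, ratio, grid, partition)
            try:
                coeffs = solve_sparse_regression(problem, spec, solver_config)
            except Exception as err:
                raise RuntimeError(
                    f"solver failed for centroid ROI {m} at ratio {ratio}: {err}"
                ) from err
            incidence[build_hyperedge(coeffs, m), col] = 1
            meta.append({"centroid": m, "ratio": ratio, "method": method})
            col += 1
    return Hypergraph(n_nodes=n, incidence=incidence, edge_meta=meta)


def node_degree(H: Hypergraph, v: int) -> int:
    """Number of hyperedges containing node v (row sum of the incidence)."""
    if not 0 <= v < H.n_nodes:
        raise IndexError(f"node {v} out of range")
    return int(H.incidence[v].sum())


def edge_degree(H: Hypergraph, e: int) -> int:
    """Number of nodes in hyperedge e (column sum of the incidence)."""
    if not 0 <= e < H.n_edges:
        raise IndexError(f"edge {e} out of range")
    return int(H.incidence[:, e].sum())


def edge_degree_distribution(
    H: Hypergraph, bins: Sequence[tuple[int, float]] = DEFAULT_BINS
) -> dict:
    """Fraction of hyperedges per edge-degree bin.

    Proportions are denominated by edges of degree >= 2 (singleton edges from
    all-zero solutions are real columns but carry no connectivity); the raw
    histogram over all edges is returned alongside.
    """
    lows = [b[0] for b in bins]
    highs = [b[1] for b in bins]
    for i in range(len(bins) - 1):
        if highs[i] >= lows[i + 1]:
            raise ValueError("bins must be disjoint and increasing")
    deg = H.edge_degrees()
    denom = int((deg >= 2).sum())
    proportions = {}
    for lo, hi in bins:
        count = int(((deg >= lo) & (deg <= hi)).sum())
        label = f"{lo}-{int(hi)}" if np.isfinite(hi) else f"{lo}+"
        proportions[label] = count / denom if denom else 0.0
    raw = np.bincount(deg, minlength=2)
    return {"proportions": proportions, "n_edges_ge2": denom, "raw_histogram": raw}
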