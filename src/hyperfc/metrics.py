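"""Hypergraph clustering coefficients and per-subject feature assembly.

Two families of local node attributes are extracted from each subject's
hypergraph.

Single-node coefficients (HCC1-3), with N(v) the neighbors of v (nodes
sharing at least one hyperedge with v) and S(v) the hyperedges containing v:

* HCC1: fraction of neighbor pairs co-occurring in some hyperedge that does
  NOT contain v (connections not facilitated by v).
* HCC2: fraction of neighbor pairs co-occurring with v in a single hyperedge
  (connections facilitated by v).
* HCC3: 2 * (sum_{e in S(v)} (|e|-1) - |N(v)|) / (|N(v)| * (|S(v)|-1)),
  the multiplicity excess of neighbor slots over distinct neighbors, i.e.
  the amount of overlap among v's incident hyperedges.

Pairwise ("mutual") coefficients COMHCC1-5 compare incident-edge sets of a
node pair: Jaccard, meet/max, meet/min, meet over the geometric mean, and the
negative log of the hypergeometric upper-tail probability of the observed
overlap (population = all hyperedges of the subject's hypergraph).  Each is
node-averaged over N(v).

All divide-by-zero guards return 0 so feature matrices stay finite even for
nodes that fall in a single hyperedge.  S(v) is a set of edge IDs, so
duplicate incidence columns count separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .hypernetwork import Hypergraph

__all__ = [
    "NodeNeighborhood",
    "FeatureTable",
    "neighborhood",
    "hcc1",
    "hcc2",
    "hcc3",
    "comhcc_pair",
    "comhcc_node",
    "subject_features",
    "feature_names",
    "build_feature_table",
]

HCC_KINDS = (1, 2, 3)
COMHCC_KINDS = (1, 2, 3, 4, 5)
_PROB_FLOOR = 1e-300


@dataclass
class NodeNeighborhood:
    node: int
    neighbors: np.ndarray  # N(v), sorted, excludes v
    incident_edges: np.ndarray  # S(v), edge ids


def neighborhood(H: Hypergraph, v: int) -> NodeNeighborhood:
    """N(v) = other nodes sharing an edge with v; S(v) = edges containing v."""
    edges = np.flatnonzero(H.incidence[v])
    if edges.size:
        nodes = np.flatnonzero(H.incidence[:, edges].any(axis=1))
        nodes = nodes[nodes != v]
    else:
        nodes = np.array([], dtype=int)
    return NodeNeighborhood(node=v, neighbors=nodes, incident_edges=edges)


def _pair_fraction(H: Hypergraph, v: int, facilitated: bool) -> float:
    nb = neighborhood(H, v)
    n = nb.neighbors.size
    if n < 2:
        return 0.0
    if facilitated:
        cols = H.incidence[:, nb.incident_edges].astype(np.int64)
    else:
        mask = np.ones(H.n_edges, dtype=bool)
        mask[nb.incident_edges] = False
        cols = H.incidence[:, mask].astype(np.int64)
    co = cols @ cols.T  # pair co-occurrence counts over the selected edges
    sub = co[np.ix_(nb.neighbors, nb.neighbors)]
    iu = np.triu_indices(n, k=1)
    covered = int((sub[iu] > 0).sum())
    return 2.0 * covered / (n * (n - 1))


def hcc1(H: Hypergraph, v: int) -> float:
    """Neighbor pairs connected by an edge avoiding v, over all pairs."""
    return _pair_fraction(H, v, facilitated=False)


def hcc2(H: Hypergraph, v: int) -> float:
    """Neighbor pairs co-occurring with v in one edge, over all pairs."""
    return _pair_fraction(H, v, facilitated=True)


def hcc3(H: Hypergraph, v: int) -> float:
    """Overlap among v's incident hyperedges; 0 when |S(v)| <= 1 or N(v) empty."""
    nb = neighborhood(H, v)
    n_nb, n_edges = nb.neighbors.size, nb.incident_edges.size
    if n_edges <= 1 or n_nb == 0:
        return 0.0
    slot_sum = int(H.incidence[:, nb.incident_edges].sum() - n_edges)  # sum(|e|-1)
    return 2.0 * (slot_sum - n_nb) / (n_nb * (n_edges - 1))


def comhcc_pair(H: Hypergraph, u: int, v: int, kind: int) -> float:
    """Pairwise mutual clustering coefficient of the given kind (1..5)."""
    if kind not in COMHCC_KINDS:
        raise ValueError(f"kind must be one of {COMHCC_KINDS}")
    if u == v:
        raise ValueError("u and v must differ")
    su = np.flatnonzero(H.incidence[u])
    sv = np.flatnonzero(H.incidence[v])
    if su.size == 0 or sv.size == 0:
        return 0.0
    inter = np.intersect1d(su, sv, assume_unique=True).size
    if kind == 1:
        return inter / np.union1d(su, sv).size
    if kind == 2:
        return inter / max(su.size, sv.size)
    if kind == 3:
        return inter / min(su.size, sv.size)
    if kind == 4:
        return inter / np.sqrt(su.size * sv.size)
    total = H.n_edges
    # P(overlap >= observed) when sv.size edges are drawn from total, su.size
    # of which are marked.
    p = float(hypergeom.sf(inter - 1, total, su.size, sv.size))
    return -np.log(min(max(p, _PROB_FLOOR), 1.0))


def comhcc_node(H: Hypergraph, v: int, kind: int) -> float:
    """Node-averaged pairwise coefficient: mean over u in N(v); 0 if isolated."""
    nb = neighborhood(H, v)
    if nb.neighbors.size == 0:
        return 0.0
    return float(np.mean([comhcc_pair(H, u, v, kind) for u in nb.neighbors]))


def subject_features(H: Hypergraph) -> np.ndarray:
    """Feature row: 3*n HCC values then 5*n COMHCC values, metric-major."""
    n = H.n_nodes
    hcc_funcs = (hcc1, hcc2, hcc3)
    out = np.empty(3 * n + 5 * n)
    for j, f in enumerate(hcc_funcs):
        out[j * n : (j + 1) * n] = [f(H, v) for v in range(n)]
    base = 3 * n
    for j, kind in enumerate(COMHCC_KINDS):
        out[base + j * n : base + (j + 1) * n] = [
            comhcc_node(H, v, kind) for v in range(n)
        ]
    return out


def feature_names(n_nodes: int) -> list[str]:
    names = [f"HCC{j}_roi_{v}" for j in HCC_KINDS for v in range(n_nodes)]
    names += [f"COMHCC{j}_roi_{v}" for j in COMHCC_KINDS for v in range(n_nodes)]
    return names


@dataclass
class FeatureTable:
    """Subjects x features matrix of clustering coefficients with labels.

    The first 3*n columns are the single-node family (HCC), the following
    5*n the pairwise family (COMHCC); for the default 90-node atlas that is
    270 + 450 attributes.
    """

    subjects: list[str]
    labels: np.ndarray
    values: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), 8 * self.n_nodes):
            raise ValueError("values must be n_subjects x 8*n_nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def hcc_block(self) -> np.ndarray:
        return self.values[:, : 3 * self.n_nodes]

    @property
    def comhcc_block(self) -> np.ndarray:
        return self.values[:, 3 * self.n_nodes :]

    @property
    def column_names(self) -> list[str]:
        return feature_names(self.n_nodes)

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subjects)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        values = df.drop(columns=["subject_id", "label"]).to_numpy(dtype=float)
        n_nodes = values.shape[1] // 8
        return cls(
            subjects=df["subject_id"].tolist(),
            labels=df["label"].to_numpy(),
            values=values,
            n_nodes=n_nodes,
        )


def build_feature_table(
    hypergraphs: Sequence[Hypergraph],
    subjects: Sequence[str],
    labels: Sequence[str],
) -> FeatureTable:
    values = np.vstack([subject_features(H) for H in hypergraphs])
    return FeatureTable(
        subjects=list(subjects),
        labels=np.asarray(labels),
        values=values,
        n_nodes=hypergraphs[0].n_nodes,
    )
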