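"""Independent brute-force reference implementations used only by tests.

Each function is written directly from the defining formula using Python
sets and explicit loops, independent of the package's vectorized code paths.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def edge_sets(incidence: np.ndarray) -> list[frozenset[int]]:
    return [frozenset(np.flatnonzero(incidence[:, e])) for e in range(incidence.shape[1])]


def S(incidence: np.ndarray, v: int) -> set[int]:
    return {e for e, members in enumerate(edge_sets(incidence)) if v in members}


def N(incidence: np.ndarray, v: int) -> set[int]:
    out: set[int] = set()
    for members in edge_sets(incidence):
        if v in members:
            out |= members
    return out - {v}


def hcc1_brute(incidence: np.ndarray, v: int) -> float:
    nv = sorted(N(incidence, v))
    if len(nv) < 2:
        return 0.0
    edges = edge_sets(incidence)
    count = sum(
        1
        for u, t in combinations(nv, 2)
        if any(u in e and t in e and v not in e for e in edges)
    )
    return 2.0 * count / (len(nv) * (len(nv) - 1))


def hcc2_brute(incidence: np.ndarray, v: int) -> float:
    nv = sorted(N(incidence, v))
    if len(nv) < 2:
        return 0.0
    edges = edge_sets(incidence)
    count = sum(
        1
        for u, t in combinations(nv, 2)
        if any(u in e and t in e and v in e for e in edges)
    )
    return 2.0 * count / (len(nv) * (len(nv) - 1))


def hcc3_brute(incidence: np.ndarray, v: int) -> float:
    sv = S(incidence, v)
    nv = N(incidence, v)
    if len(sv) <= 1 or len(nv) == 0:
        return 0.0
    edges = edge_sets(incidence)
    slot_sum = sum(len(edges[e]) - 1 for e in sv)
    return 2.0 * (slot_sum - len(nv)) / (len(nv) * (len(sv) - 1))


def comhcc_pair_brute(incidence: np.ndarray, u: int, v: int, kind: int) -> float:
    su, sv = S(incidence, u), S(incidence, v)
    if not su or not sv:
        return 0.0
    inter = len(su & sv)
    if kind == 1:
        return inter / len(su | sv)
    if kind == 2:
        return inter / max(len(su), len(sv))
    if kind == 3:
        return inter / min(len(su), len(sv))
    if kind == 4:
        return inter / math.sqrt(len(su) * len(sv))
    if kind == 5:
        total = incidence.shape[1]
        p = sum(
            math.comb(len(su), i) * math.comb(total - len(su), len(sv) - i)
            for i in range(inter, min(len(su), len(sv)) + 1)
        ) / math.comb(total, len(sv))
        return -math.log(min(max(p, 1e-300), 1.0))
    raise ValueError(kind)


def comhcc_node_brute(incidence: np.ndarray, v: int, kind: int) -> float:
    nv = N(incidence, v)
    if not nv:
        return 0.0
    return sum(comhcc_pair_brute(incidence, u, v, kind) for u in nv) / len(nv)


def ks_brute(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_a - ECDF_b| by evaluating at every pooled point."""
    points = np.concatenate([a, b])
    return max(
        abs((a <= x).mean() - (b <= x).mean()) for x in points
    )


def bh_brute(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Step-up BH from the definition."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k_star = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def sgl_objective(X, y, a, lam1, lam2, groups) -> float:
    resid = y - X @ a
    pen = lam1 * np.abs(a).sum() + lam2 * sum(
        np.linalg.norm(a[g]) for g in groups
    )
    return 0.5 * float(resid @ resid) + pen
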