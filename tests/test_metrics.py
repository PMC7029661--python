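"""Hypergraph clustering coefficients against brute-force set enumeration."""

import itertools

import numpy as np
import pytest

from hyperfc.hypernetwork import Hypergraph
from hyperfc.metrics import (
    COMHCC_KINDS,
    comhcc_node,
    comhcc_pair,
    hcc1,
    hcc2,
    hcc3,
    neighborhood,
    subject_features,
    feature_names,
)

import oracles


def test_neighborhood_toy(toy_hypergraph):
    nb = neighborhood(toy_hypergraph, 0)
    assert set(nb.neighbors) == {1, 2}
    assert set(nb.incident_edges) == {0, 1}
    nb3 = neighborhood(toy_hypergraph, 3)
    assert set(nb3.neighbors) == {2}
    assert set(nb3.incident_edges) == {2}


def test_neighborhood_isolated_node():
    H = Hypergraph(n_nodes=3, incidence=np.array([[1], [1], [0]], dtype=np.uint8))
    nb = neighborhood(H, 2)
    assert nb.neighbors.size == 0 and nb.incident_edges.size == 0


def test_hcc_values_on_toy(toy_hypergraph):
    # pair (1,2) co-occurs only in e0 which contains node 0
    assert hcc1(toy_hypergraph, 0) == 0.0
    assert hcc2(toy_hypergraph, 0) == 1.0
    # S(0) = {e0, e1}: slot sum (3-1)+(2-1)=3, |N|=2 -> 2*(3-2)/(2*1) = 1
    assert hcc3(toy_hypergraph, 0) == 1.0


def test_hcc_triangle_graph():
    """Three 2-edges forming a triangle: neighbors of any node are connected
    only by edges avoiding it."""
    inc = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=np.uint8)
    H = Hypergraph(n_nodes=3, incidence=inc)
    assert hcc1(H, 0) == 1.0
    assert hcc2(H, 0) == 0.0


def test_hcc3_duplicate_incident_edges():
    # two identical edges {v,u}: slot sum 2, |N|=1, |S|=2 -> 2*(2-1)/(1*1)=2
    inc = np.array([[1, 1], [1, 1]], dtype=np.uint8)
    H = Hypergraph(n_nodes=2, incidence=inc)
    assert hcc3(H, 0) == 2.0


def test_guards_return_zero():
    # node in exactly one edge -> hcc3 guard; single neighbor -> hcc1/2 guard
    inc = np.array([[1], [1], [0]], dtype=np.uint8)
    H = Hypergraph(n_nodes=3, incidence=inc)
    for f in (hcc1, hcc2, hcc3):
        assert f(H, 0) == 0.0
        assert f(H, 2) == 0.0  # isolated


def test_comhcc_pair_identical_and_disjoint(toy_hypergraph):
    # S(0) == S(1) = {e0,e1} -> Jaccard 1; S(1) vs S(3) disjoint -> 0
    assert comhcc_pair(toy_hypergraph, 0, 1, 1) == 1.0
    assert comhcc_pair(toy_hypergraph, 1, 3, 1) == 0.0


def test_comhcc_pair_partial_overlap(toy_hypergraph):
    # S(0)={e0,e1}, S(2)={e0,e2}: inter 1, union 3
    assert comhcc_pair(toy_hypergraph, 0, 2, 1) == pytest.approx(1 / 3)
    assert comhcc_pair(toy_hypergraph, 0, 2, 2) == pytest.approx(1 / 2)
    assert comhcc_pair(toy_hypergraph, 0, 2, 3) == pytest.approx(1 / 2)
    assert comhcc_pair(toy_hypergraph, 0, 2, 4) == pytest.approx(1 / 2)
    # hypergeometric tail with Total=3 edges: P(overlap >= 1) = 1 -> -log 1 = 0
    assert comhcc_pair(toy_hypergraph, 0, 2, 5) == pytest.approx(0.0, abs=1e-12)


def test_comhcc_node_toy(toy_hypergraph):
    # node 3: single neighbor 2; |S(3) ∩ S(2)| = 1, union 2 -> 0.5
    assert comhcc_node(toy_hypergraph, 3, 1) == pytest.approx(0.5)


def test_comhcc_invalid_kind(toy_hypergraph):
    with pytest.raises(ValueError):
        comhcc_pair(toy_hypergraph, 0, 1, 6)
    with pytest.raises(ValueError):
        comhcc_pair(toy_hypergraph, 0, 0, 1)


def _all_small_hypergraphs(n_nodes=4, max_edges=3):
    """Every hypergraph on n_nodes with 0..max_edges (non-empty) edges,
    allowing duplicate edges."""
    possible_edges = []
    for size in range(1, n_nodes + 1):
        possible_edges.extend(itertools.combinations(range(n_nodes), size))
    for n_edges in range(0, max_edges + 1):
        for combo in itertools.combinations_with_replacement(possible_edges, n_edges):
            inc = np.zeros((n_nodes, n_edges), dtype=np.uint8)
            for e, members in enumerate(combo):
                inc[list(members), e] = 1
            yield Hypergraph(n_nodes=n_nodes, incidence=inc)


def test_exhaustive_small_hypergraph_oracle():
    """Every metric equals the brute-force set implementation on all
    hypergraphs with <= 4 nodes and <= 3 edges (sampled exhaustively for the
    single-node metrics; pairwise checked on every graph for every pair)."""
    count = 0
    for H in _all_small_hypergraphs(4, 3):
        inc = H.incidence
        for v in range(4):
            assert hcc1(H, v) == pytest.approx(oracles.hcc1_brute(inc, v))
            assert hcc2(H, v) == pytest.approx(oracles.hcc2_brute(inc, v))
            assert hcc3(H, v) == pytest.approx(oracles.hcc3_brute(inc, v))
            for kind in COMHCC_KINDS:
                assert comhcc_node(H, v, kind) == pytest.approx(
                    oracles.comhcc_node_brute(inc, v, kind)
                )
        count += 1
    assert count > 100  # the enumeration actually covered many graphs


def test_metric_ranges_random():
    rng = np.random.default_rng(5)
    for _ in range(20):
        inc = (rng.random((6, 8)) < 0.4).astype(np.uint8)
        H = Hypergraph(n_nodes=6, incidence=inc)
        for v in range(6):
            assert 0.0 <= hcc1(H, v) <= 1.0
            assert 0.0 <= hcc2(H, v) <= 1.0
            assert hcc3(H, v) >= 0.0
            for kind in (1, 2, 3, 4):
                assert 0.0 <= comhcc_node(H, v, kind) <= 1.0 + 1e-12
            assert comhcc_node(H, v, 5) >= -1e-12


def test_comhcc_pair_symmetry():
    rng = np.random.default_rng(7)
    inc = (rng.random((5, 7)) < 0.5).astype(np.uint8)
    H = Hypergraph(n_nodes=5, incidence=inc)
    for u, v in itertools.combinations(range(5), 2):
        for kind in COMHCC_KINDS:
            assert comhcc_pair(H, u, v, kind) == pytest.approx(
                comhcc_pair(H, v, u, kind)
            )


def test_permutation_equivariance():
    """Relabeling nodes permutes each metric block of the feature vector."""
    rng = np.random.default_rng(3)
    inc = (rng.random((5, 6)) < 0.5).astype(np.uint8)
    H = Hypergraph(n_nodes=5, incidence=inc)
    perm = rng.permutation(5)
    Hp = Hypergraph(n_nodes=5, incidence=inc[perm])
    f, fp = subject_features(H), subject_features(Hp)
    n = 5
    for block in range(8):
        orig = f[block * n : (block + 1) * n]
        permuted = fp[block * n : (block + 1) * n]
        # node v of Hp is node perm[v] of H
        assert permuted == pytest.approx(orig[perm])


def test_subject_features_shape_and_no_edges():
    H = Hypergraph(n_nodes=6, incidence=np.zeros((6, 0), dtype=np.uint8))
    f = subject_features(H)
    assert f.shape == (48,)
    assert np.all(f == 0.0)
    assert len(feature_names(90)) == 270 + 450
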