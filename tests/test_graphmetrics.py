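"""Graph metrics against an exhaustive path-enumeration oracle, closed
forms, equivariances and node-level permutation inference."""

import itertools

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from gcnet.graphmetrics import (degree_centralities, global_efficiency,
                                local_efficiency, node_significance)


# --- independent oracle: enumerate every simple path -----------------------

def brute_shortest_distance(A, i, j):
    """Minimum total length (sum of 1/weight) over all simple paths i -> j."""
    n = A.shape[0]
    best = np.inf
    others = [k for k in range(n) if k not in (i, j)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (i, *mid, j)
            length = 0.0
            for a, b in zip(path[:-1], path[1:]):
                if A[a, b] == 0:
                    length = np.inf
                    break
                length += 1.0 / A[a, b]
            best = min(best, length)
    return best


def brute_global_efficiency(A):
    n = A.shape[0]
    if n < 2:
        return 0.0
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = brute_shortest_distance(A, i, j)
            acc += 0.0 if np.isinf(d) else 1.0 / d
    return acc / (n * (n - 1))


def brute_local_efficiency(A):
    n = A.shape[0]
    acc = 0.0
    for i in range(n):
        nbrs = [j for j in range(n)
                if j != i and (A[i, j] > 0 or A[j, i] > 0)]
        if len(nbrs) < 2:
            continue
        acc += brute_global_efficiency(A[np.ix_(nbrs, nbrs)])
    return acc / n


def random_digraph(rng, n, density=0.4):
    A = rng.uniform(0.1, 2.0, size=(n, n)) * (rng.random((n, n)) < density)
    np.fill_diagonal(A, 0.0)
    return A


class TestEfficiencyOracle:
    def test_matches_exhaustive_enumeration_on_random_digraphs(self):
        rng = np.random.default_rng(12)
        for trial in range(50):
            n = int(rng.integers(6, 9))
            A = random_digraph(rng, n)
            assert global_efficiency(A) == pytest.approx(
                brute_global_efficiency(A), abs=1e-12)

    def test_local_efficiency_matches_enumeration(self):
        rng = np.random.default_rng(13)
        for trial in range(10):
            A = random_digraph(rng, 6)
            assert local_efficiency(A) == pytest.approx(
                brute_local_efficiency(A), abs=1e-12)

    def test_complete_uniform_graph_has_ge_and_le_equal_weight(self):
        for w in (0.5, 2.0):
            A = np.full((5, 5), w)
            np.fill_diagonal(A, 0.0)
            assert global_efficiency(A) == pytest.approx(w, abs=1e-12)
            assert local_efficiency(A) == pytest.approx(w, abs=1e-12)

    def test_edgeless_graph_has_zero_efficiency(self):
        A = np.zeros((6, 6))
        assert global_efficiency(A) == 0.0
        assert local_efficiency(A) == 0.0

    def test_star_digraph_has_zero_local_efficiency(self):
        # hub <-> leaves only: hub neighbors share no edges, leaves have 1
        A = np.zeros((5, 5))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        assert local_efficiency(A) == 0.0
        assert global_efficiency(A) > 0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(14)
        A = random_digraph(rng, 7)
        for c in (0.25, 3.0):
            assert global_efficiency(c * A) == pytest.approx(
                c * global_efficiency(A), rel=1e-12)
            assert local_efficiency(c * A) == pytest.approx(
                c * local_efficiency(A), rel=1e-12)

    def test_adding_an_edge_never_decreases_ge(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            A = random_digraph(rng, 6, density=0.3)
            zeros = np.argwhere((A == 0) & ~np.eye(6, dtype=bool))
            if zeros.size == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            B = A.copy()
            B[i, j] = rng.uniform(0.1, 2.0)
            assert global_efficiency(B) >= global_efficiency(A) - 1e-12

    def test_negative_weight_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = -0.5
        with pytest.raises(ValueError):
            global_efficiency(A)


class TestDegreeCentrality:
    def test_single_edge(self):
        A = np.zeros((2, 2))
        A[0, 1] = 0.7
        nc = degree_centralities(A)
        assert np.allclose(nc.outdegree, [0.7, 0.0])
        assert np.allclose(nc.indegree, [0.0, 0.7])

    def test_double_count_identity(self):
        rng = np.random.default_rng(16)
        A = random_digraph(rng, 9)
        nc = degree_centralities(A)
        assert nc.outdegree.sum() == pytest.approx(A.sum())
        assert nc.indegree.sum() == pytest.approx(A.sum())

    def test_hand_computed_row_and_column_sums(self):
        A = np.array([[0.0, 0.010, 0.000, 0.004],
                      [0.002, 0.0, 0.006, 0.000],
                      [0.000, 0.003, 0.0, 0.005],
                      [0.001, 0.000, 0.002, 0.0]])
        nc = degree_centralities(A)
        assert np.allclose(nc.outdegree, [0.014, 0.008, 0.008, 0.003])
        assert np.allclose(nc.indegree, [0.003, 0.013, 0.008, 0.009])


class TestNodeSignificance:
    def test_identical_groups_yield_empty_set(self):
        vals = np.tile(np.linspace(1, 2, 10), (8, 1))
        sig = node_significance(vals, vals, "outdegree", n_perm=200, seed=0)
        assert sig.significant_nodes == []

    def test_three_sd_separation_survives_bonferroni_68(self):
        rng = np.random.default_rng(17)
        low = rng.standard_normal((25, 68))
        high = rng.standard_normal((25, 68))
        low[:, 30] += 3.0  # 3 pooled SDs at one node
        sig = node_significance(low, high, "outdegree", n_perm=2000, seed=1)
        assert sig.labels[30] in sig.significant_nodes

    def test_bonferroni_set_is_subset_of_uncorrected(self):
        rng = np.random.default_rng(18)
        low = rng.standard_normal((15, 20))
        high = rng.standard_normal((15, 20)) + 0.4
        sig = node_significance(low, high, "indegree", n_perm=500, seed=2)
        uncorrected = {sig.labels[i] for i in range(20)
                       if sig.p_raw[i] < sig.alpha}
        assert set(sig.significant_nodes) <= uncorrected

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            node_significance(np.zeros((3, 4)), np.zeros((3, 4)), "degree")


class TestEfficiencyProperties:
    """Invariants checked over generated weighted digraphs."""

    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    @seed(2024)
    def test_scale_equivariance_property(self, graph_seed, c):
        rng = np.random.default_rng(graph_seed)
        A = random_digraph(rng, int(rng.integers(3, 8)))
        assert global_efficiency(c * A) == pytest.approx(
            c * global_efficiency(A), rel=1e-9)
        assert local_efficiency(c * A) == pytest.approx(
            c * local_efficiency(A), rel=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    @seed(2025)
    def test_edge_addition_monotonicity_property(self, graph_seed):
        rng = np.random.default_rng(graph_seed)
        n = int(rng.integers(4, 8))
        A = random_digraph(rng, n, density=0.3)
        zeros = np.argwhere((A == 0) & ~np.eye(n, dtype=bool))
        if zeros.size == 0:
            return
        i, j = zeros[rng.integers(len(zeros))]
        B = A.copy()
        B[i, j] = rng.uniform(0.1, 2.0)
        assert global_efficiency(B) >= global_efficiency(A) - 1e-12
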