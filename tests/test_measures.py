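"""Graph measures against exhaustive brute-force oracles and closed-form cases."""

import itertools

import numpy as np
import pytest

from connharm.io import MEAN_LENGTH, STREAMLINE_COUNT, ConnectivityMatrix
from connharm.measures import (
    DegenerateMatrixError,
    avg_betweenness,
    compute_all,
    global_efficiency,
    modularity,
    modularity_partition,
    normalize_counts,
    partition_quality,
)
from conftest import random_symmetric, small_manifest


# ---------------------------------------------------------------- oracles


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def brute_force_max_modularity(w):
    """Maximal Q over every partition of the nodes."""
    n = w.shape[0]
    best = -np.inf
    for part in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, nodes in enumerate(part):
            labels[nodes] = c
        best = max(best, partition_quality(w, labels))
    return best


def brute_force_paths(lengths):
    """Exhaustive shortest paths: for each ordered (s, t), the minimal cost,
    the number of minimal paths, and per-node pass-through counts.

    Integer edge lengths keep float path costs exact, so tie detection is exact.
    """
    n = lengths.shape[0]
    out = {}
    for s, t in itertools.permutations(range(n), 2):
        best_cost, best_paths = np.inf, []

        def dfs(node, visited, cost, interior):
            nonlocal best_cost, best_paths
            if cost > best_cost:
                return
            if node == t:
                if cost < best_cost:
                    best_cost, best_paths = cost, [list(interior)]
                elif cost == best_cost:
                    best_paths.append(list(interior))
                return
            for nxt in range(n):
                if lengths[node, nxt] > 0 and nxt not in visited:
                    dfs(
                        nxt,
                        visited | {nxt},
                        cost + lengths[node, nxt],
                        interior + ([node] if node != s else []),
                    )

        dfs(s, {s}, 0.0, [])
        through = np.zeros(n)
        for path in best_paths:
            for v in path:
                through[v] += 1
        out[(s, t)] = (best_cost, len(best_paths), through)
    return out


def brute_force_global_efficiency(w):
    """E from exhaustive path enumeration with lengths 1/w."""
    n = w.shape[0]
    lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    sp = brute_force_paths(lengths)
    total = sum(1.0 / d for d, _, _ in sp.values() if np.isfinite(d))
    return total / (n * (n - 1))


def brute_force_avg_betweenness(lengths):
    """Mean node betweenness from exhaustive enumeration, ordered pairs."""
    n = lengths.shape[0]
    sp = brute_force_paths(lengths)
    bc = np.zeros(n)
    for (s, t), (d, sigma, through) in sp.items():
        if np.isfinite(d) and sigma > 0:
            bc += through / sigma
    return float(bc.mean())


def random_integer_graph(rng, n, density=0.7, max_w=8):
    """Random connected-ish symmetric integer-weight graph, zero diagonal."""
    w = rng.integers(1, max_w + 1, size=(n, n)).astype(float)
    w *= rng.random((n, n)) < density
    w = np.triu(w, k=1)
    return w + w.T


# ---------------------------------------------------------------- unit cases


class TestNormalizeCounts:
    def test_scales_by_maximum(self):
        m = ConnectivityMatrix("s", STREAMLINE_COUNT, np.array([[0.0, 4.0], [4.0, 0.0]]))
        out = normalize_counts(m)
        np.testing.assert_array_equal(out.values, [[0.0, 1.0], [1.0, 0.0]])

    def test_idempotent_at_max_one(self, rng):
        v = random_symmetric(rng, 5, scale=1.0)
        v /= v.max()
        m = ConnectivityMatrix("s", STREAMLINE_COUNT, v)
        np.testing.assert_array_equal(normalize_counts(m).values, v)

    def test_all_zero_errors(self):
        m = ConnectivityMatrix("s", STREAMLINE_COUNT, np.zeros((3, 3)))
        with pytest.raises(DegenerateMatrixError):
            normalize_counts(m)


class TestModularity:
    def test_two_disconnected_cliques(self):
        """Two 3-node unit-weight cliques: the optimal split has Q = 1/2."""
        w = np.zeros((6, 6))
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        m = ConnectivityMatrix("s", STREAMLINE_COUNT, w)
        assert modularity(m) == pytest.approx(0.5, abs=1e-12)
        assert brute_force_max_modularity(w) == pytest.approx(0.5, abs=1e-12)

    def test_complete_graph_single_community(self):
        """No split of a complete graph improves on Q = 0."""
        w = 1.0 - np.eye(4)
        m = ConnectivityMatrix("s", STREAMLINE_COUNT, w)
        assert modularity(m) == pytest.approx(0.0, abs=1e-12)
        assert brute_force_max_modularity(w) == pytest.approx(0.0, abs=1e-12)
        assert len(np.unique(modularity_partition(m))) == 1

    def test_permutation_invariance(self, rng):
        w = random_integer_graph(rng, 7)
        perm = rng.permutation(7)
        q1 = modularity(ConnectivityMatrix("s", STREAMLINE_COUNT, w))
        q2 = modularity(ConnectivityMatrix("s", STREAMLINE_COUNT, w[np.ix_(perm, perm)]))
        assert q1 == pytest.approx(q2, abs=1e-10)

    def test_scale_invariance(self, rng):
        w = random_integer_graph(rng, 8)
        q1 = modularity(ConnectivityMatrix("s", STREAMLINE_COUNT, w))
        q2 = modularity(ConnectivityMatrix("s", STREAMLINE_COUNT, 137.5 * w))
        assert q1 == pytest.approx(q2, rel=1e-10)

    def test_matches_independent_quality_formula(self, rng):
        import networkx as nx

        w = random_integer_graph(rng, 8)
        m = ConnectivityMatrix("s", STREAMLINE_COUNT, w)
        labels = modularity_partition(m)
        g = nx.from_numpy_array(w)
        comms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        q_nx = nx.algorithms.community.modularity(g, comms, weight="weight")
        assert modularity(m) == pytest.approx(q_nx, abs=1e-10)

    def test_all_zero_errors(self):
        with pytest.raises(DegenerateMatrixError):
            modularity(ConnectivityMatrix("s", STREAMLINE_COUNT, np.zeros((4, 4))))


class TestGlobalEfficiency:
    def test_complete_unit_graph_is_one(self):
        w = 1.0 - np.eye(5)
        assert global_efficiency(ConnectivityMatrix("s", STREAMLINE_COUNT, w)) == 1.0

    def test_edgeless_graph_is_zero(self):
        w = np.zeros((4, 4))
        assert global_efficiency(ConnectivityMatrix("s", STREAMLINE_COUNT, w)) == 0.0

    def test_three_node_path(self):
        """Unit-weight path: four ordered pairs at d=1, two at d=2 -> E = 5/6."""
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        e = global_efficiency(ConnectivityMatrix("s", STREAMLINE_COUNT, w))
        assert e == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_scale_invariance_after_normalization(self, rng):
        w = random_integer_graph(rng, 8)
        e1 = global_efficiency(normalize_counts(ConnectivityMatrix("s", STREAMLINE_COUNT, w)))
        e2 = global_efficiency(normalize_counts(ConnectivityMatrix("s", STREAMLINE_COUNT, 3.7 * w)))
        assert e1 == pytest.approx(e2, rel=1e-12)


class TestAvgBetweenness:
    def test_three_node_path(self):
        w = np.array([[0, 30, 0], [30, 0, 45], [0, 45, 0]], dtype=float)
        b = avg_betweenness(ConnectivityMatrix("s", MEAN_LENGTH, w))
        assert b == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_star_center(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 50.0
        b = avg_betweenness(ConnectivityMatrix("s", MEAN_LENGTH, w))
        assert b == pytest.approx(12.0 / 5.0, abs=1e-12)

    def test_complete_equal_lengths_zero(self):
        w = 60.0 * (1.0 - np.eye(6))
        assert avg_betweenness(ConnectivityMatrix("s", MEAN_LENGTH, w)) == 0.0

    def test_too_small_errors(self):
        with pytest.raises(DegenerateMatrixError):
            avg_betweenness(ConnectivityMatrix("s", MEAN_LENGTH, np.array([[0.0, 1.0], [1.0, 0.0]])))


class TestBruteForceOracles:
    """Exhaustive cross-checks on small random graphs (the oracle suite)."""

    def test_modularity_never_exceeds_brute_force_optimum(self):
        rng = np.random.default_rng(7)
        checked = 0
        for n in (4, 5, 6, 7):
            for _ in range(50):
                w = random_integer_graph(rng, n)
                if w.sum() == 0:
                    continue
                m = ConnectivityMatrix("s", STREAMLINE_COUNT, w)
                q = modularity(m)
                q_max = brute_force_max_modularity(w)
                assert q <= q_max + 1e-10
                # returned Q is the true quality of the returned partition
                assert q == pytest.approx(partition_quality(w, modularity_partition(m)), abs=1e-12)
                checked += 1
        assert checked >= 195

    def test_global_efficiency_matches_path_enumeration(self):
        rng = np.random.default_rng(11)
        checked = 0
        for n in (4, 5, 6, 7):
            for _ in range(50):
                w = random_integer_graph(rng, n, density=0.6)
                e = global_efficiency(ConnectivityMatrix("s", STREAMLINE_COUNT, w))
                assert e == pytest.approx(brute_force_global_efficiency(w), abs=1e-10)
                checked += 1
        assert checked >= 200

    def test_betweenness_matches_path_enumeration(self):
        rng = np.random.default_rng(13)
        checked = 0
        for n in (4, 5, 6, 7):
            for _ in range(50):
                w = random_integer_graph(rng, n, density=0.6, max_w=5)
                if (w.sum(axis=1) > 0).sum() < 3:
                    continue
                b = avg_betweenness(ConnectivityMatrix("s", MEAN_LENGTH, w))
                assert b == pytest.approx(brute_force_avg_betweenness(w), abs=1e-10)
                checked += 1
        assert checked >= 195


class TestComputeAll:
    def test_row_count_and_determinism(self, tiny_cohort):
        mats, man = tiny_cohort
        t1 = compute_all(mats, man)
        t2 = compute_all(mats, man)
        assert len(t1) == 3 * len(man)
        assert t1.equals(t2)
        assert set(t1["measure"]) == {"modularity", "global_efficiency", "avg_betweenness"}

    def test_missing_matrix_names_subject(self, tiny_cohort):
        mats, man = tiny_cohort
        missing = man.subject_ids[1]
        mats = [m for m in mats if not (m.subject_id == missing and m.weighting == MEAN_LENGTH)]
        with pytest.raises(ValueError, match=missing):
            compute_all(mats, man)
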