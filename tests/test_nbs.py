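"""NBS: edge-wise t, component extraction, permutation FWER, z extraction."""

import numpy as np
import pytest

from snconn import (
    ConnectivityMatrix,
    NBSConfig,
    edgewise_t,
    extract_significant_z,
    nbs_permutation_test,
    threshold_components,
    two_sample_t,
)
from snconn.nbs import TWO_SIDED


def _mats(arrays, scale="fisher_z", labels=None):
    out = []
    for k, a in enumerate(arrays):
        a = np.asarray(a, dtype=float)
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        out.append(ConnectivityMatrix(a, scale=scale, subject_id=f"s{k}",
                                      node_labels=labels))
    return out


def _random_group(rng, n_sub, n_nodes, shift=0.0, edge=None):
    arrays = []
    for _ in range(n_sub):
        a = rng.normal(0, 0.2, (n_nodes, n_nodes))
        a = (a + a.T) / 2
        if edge is not None:
            i, j = edge
            a[i, j] += shift
            a[j, i] = a[i, j]
        arrays.append(a)
    return _mats(arrays)


def brute_force_components(n_nodes, edges):
    """Exhaustive reachability oracle: set of (nodes, edges) components."""
    adj = {k: set() for k in range(n_nodes)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen, comps = set(), set()
    for start in range(n_nodes):
        if start in seen or not adj[start]:
            continue
        nodes = set()
        stack = [start]
        while stack:
            u = stack.pop()
            if u in nodes:
                continue
            nodes.add(u)
            stack.extend(adj[u] - nodes)
        seen |= nodes
        comp_edges = frozenset(
            (min(a, b), max(a, b)) for a in nodes for b in adj[a]
        )
        comps.add((frozenset(nodes), comp_edges))
    return comps


class TestEdgewiseT:
    def test_identical_groups_zero_matrix(self, rng):
        g = _random_group(rng, 4, 5)
        t = edgewise_t(g, g)
        assert np.allclose(t, 0.0)

    def test_matches_scalar_t_oracle_per_edge(self, rng):
        g1 = _random_group(rng, 8, 4)
        g2 = _random_group(rng, 9, 4, shift=0.5, edge=(1, 3))
        t = edgewise_t(g1, g2)
        for i in range(4):
            for j in range(i + 1, 4):
                x = [m.values[i, j] for m in g1]
                y = [m.values[i, j] for m in g2]
                t_ref, _, _ = two_sample_t(x, y)
                assert t[i, j] == pytest.approx(t_ref, abs=1e-10)

    def test_swapping_groups_negates(self, rng):
        g1 = _random_group(rng, 5, 4)
        g2 = _random_group(rng, 6, 4, shift=0.3, edge=(0, 2))
        assert np.allclose(edgewise_t(g1, g2), -edgewise_t(g2, g1))

    def test_mixed_scales_refused(self, rng):
        g1 = _random_group(rng, 3, 4)
        g2 = _random_group(rng, 3, 4, shift=0.0)
        g2[0].scale = "pearson_r"
        with pytest.raises(ValueError, match="scale"):
            edgewise_t(g1, g2)


class TestThresholdComponents:
    def _matrix_from_edges(self, n, edges, value=5.0):
        t = np.zeros((n, n))
        for i, j in edges:
            t[i, j] = t[j, i] = value
        return t

    def test_no_supra_threshold_edges_empty(self):
        cfg = NBSConfig(t_threshold=3.1, sidedness=TWO_SIDED)
        assert threshold_components(np.zeros((5, 5)), cfg) == []

    def test_toy_chain_matches_bfs_oracle(self):
        # edges (1-2), (2-3): one component of size 2 on nodes {1,2,3}
        t = self._matrix_from_edges(5, [(1, 2), (2, 3)])
        cfg = NBSConfig(t_threshold=3.1, sidedness=TWO_SIDED)
        comps = threshold_components(t, cfg)
        assert len(comps) == 1
        assert comps[0].size == 2
        assert comps[0].nodes == {1, 2, 3}
        oracle = brute_force_components(5, [(1, 2), (2, 3)])
        assert (frozenset(comps[0].nodes), frozenset(comps[0].edges)) in oracle

    def test_isolated_edge_is_size_one(self):
        t = self._matrix_from_edges(4, [(0, 3)])
        cfg = NBSConfig(sidedness=TWO_SIDED)
        comps = threshold_components(t, cfg)
        assert len(comps) == 1 and comps[0].size == 1

    def test_agrees_with_oracle_on_random_graphs(self):
        # exhaustive-reachability oracle over 100 random 8-node graphs
        rng = np.random.default_rng(77)
        cfg = NBSConfig(t_threshold=3.1, sidedness=TWO_SIDED)
        for _ in range(100):
            n = 8
            t = np.zeros((n, n))
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.25:
                        t[i, j] = t[j, i] = 5.0
                        edges.append((i, j))
            comps = threshold_components(t, cfg)
            got = {(frozenset(c.nodes), frozenset(c.edges)) for c in comps}
            assert got == brute_force_components(n, edges)

    def test_strict_threshold_excludes_exact_ties(self):
        t = self._matrix_from_edges(3, [(0, 1)], value=3.1)
        cfg = NBSConfig(t_threshold=3.1, sidedness=TWO_SIDED)
        assert threshold_components(t, cfg) == []

    def test_monotone_in_threshold(self, rng):
        t = rng.normal(0, 2, (10, 10))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 0)
        sizes = []
        for thr in (0.5, 1.0, 2.0, 3.0):
            comps = threshold_components(
                t, NBSConfig(t_threshold=thr, sidedness=TWO_SIDED)
            )
            sizes.append(max((c.size for c in comps), default=0))
        assert sizes == sorted(sizes, reverse=True)


class TestPermutationTest:
    def test_observed_larger_than_all_nulls_hits_floor(self, rng):
        g1 = _random_group(rng, 10, 5, shift=-3.0, edge=(0, 1))
        g1b = _random_group(rng, 10, 5, shift=-3.0, edge=(1, 2))
        for m, m2 in zip(g1, g1b):
            m.values[1, 2] = m.values[2, 1] = m2.values[1, 2]
        g2 = _random_group(rng, 10, 5)
        cfg = NBSConfig(n_permutations=200, seed=0)
        res = nbs_permutation_test(g1, g2, cfg)
        assert res.significant_components
        n_perm = len(res.null_max_sizes)
        top = res.significant_components[0]
        assert top.fwer_p >= 1.0 / (n_perm + 1)
        if np.all(res.null_max_sizes < top.size):
            assert top.fwer_p == pytest.approx(1.0 / (n_perm + 1))

    def test_fwer_p_invariant_to_node_relabeling(self, rng):
        g1 = _random_group(rng, 8, 6, shift=-1.5, edge=(0, 1))
        g2 = _random_group(rng, 8, 6)
        cfg = NBSConfig(t_threshold=2.0, n_permutations=100, seed=5)
        res = nbs_permutation_test(g1, g2, cfg)
        perm = np.random.default_rng(1).permutation(6)
        g1p = _mats([m.values[np.ix_(perm, perm)] for m in g1])
        g2p = _mats([m.values[np.ix_(perm, perm)] for m in g2])
        res_p = nbs_permutation_test(g1p, g2p, cfg)
        assert sorted(c.fwer_p for c in res.components) == pytest.approx(
            sorted(c.fwer_p for c in res_p.components)
        )

    def test_exact_enumeration_warns_when_requested_exceeds_distinct(self, rng):
        g1 = _random_group(rng, 3, 4)
        g2 = _random_group(rng, 3, 4)
        cfg = NBSConfig(n_permutations=5000, seed=0)
        with pytest.warns(UserWarning, match="distinct"):
            res = nbs_permutation_test(g1, g2, cfg)
        assert len(res.null_max_sizes) == 20  # C(6, 3)

    def test_infinite_threshold_empty_mask(self, rng):
        g1 = _random_group(rng, 5, 4, shift=-2.0, edge=(0, 1))
        g2 = _random_group(rng, 5, 4)
        res = nbs_permutation_test(
            g1, g2, NBSConfig(t_threshold=1e12, n_permutations=50, seed=0)
        )
        assert res.significant_mask.sum() == 0 and not res.components


class TestExtractSignificantZ:
    def test_all_zero_mask_empty_table(self, rng):
        g = _random_group(rng, 3, 4)
        table = extract_significant_z(np.zeros((4, 4), dtype=int), g)
        assert table.shape == (3, 0)

    def test_all_ones_mask_full_upper_triangle(self, rng):
        g = _random_group(rng, 2, 4)
        mask = 1 - np.eye(4, dtype=int)
        table = extract_significant_z(mask, g)
        iu, ju = np.triu_indices(4, k=1)
        assert table.shape == (2, 6)
        for k, m in enumerate(g):
            assert np.array_equal(table.iloc[k].to_numpy(), m.values[iu, ju])

    def test_single_edge_mask_indexes_exactly(self, rng):
        g = _random_group(rng, 4, 3)
        mask = np.zeros((3, 3), dtype=int)
        mask[1, 2] = mask[2, 1] = 1
        table = extract_significant_z(mask, g)
        for k, m in enumerate(g):
            assert table.iloc[k, 0] == m.values[1, 2]

    def test_size_mismatch_refused(self, rng):
        g = _random_group(rng, 2, 4)
        with pytest.raises(ValueError, match="mask"):
            extract_significant_z(np.zeros((3, 3), dtype=int), g)
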