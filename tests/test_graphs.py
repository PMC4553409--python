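"""Graph metrics against hand counts and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from lateralize import (BinaryGraph, binarize, global_metrics,
                        network_feature_block, nodal_metrics, random_reference)
from lateralize.connectivity import ConnectivityMatrix
from lateralize.graphs import (GLOBAL_METRICS, NODAL_METRICS, assortativity,
                               characteristic_path_length, mean_clustering,
                               transitivity)


def graph_from_edges(n, edges):
    A = np.zeros((n, n), dtype=int)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return BinaryGraph(adjacency=A)


# ---------------------------------------------------------------- oracles

def floyd_warshall(A):
    n = A.shape[0]
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def oracle_nodal(A):
    """Brute-force nodal metrics: FW distances, exhaustive triangles,
    path-enumeration betweenness."""
    n = A.shape[0]
    D = floyd_warshall(A)
    k = A.sum(axis=1)
    out = {"degree": k.astype(float)}
    spl, eg, cl, le = [], [], [], []
    for i in range(n):
        d = np.delete(D[i], i)
        reach = np.isfinite(d) & (d > 0)
        spl.append(d[reach].mean() if reach.any() else 0.0)
        eg.append(np.sum(1.0 / d[np.isfinite(d) & (d > 0)]) / (n - 1))
        nbrs = np.flatnonzero(A[i])
        t = sum(A[u, v] for u, v in itertools.combinations(nbrs, 2))
        cl.append(2.0 * t / (k[i] * (k[i] - 1)) if k[i] >= 2 else 0.0)
        if k[i] >= 2:
            sub = A[np.ix_(nbrs, nbrs)]
            Ds = floyd_warshall(sub)
            m = len(nbrs)
            inv = [1.0 / Ds[a, b] for a in range(m) for b in range(m)
                   if a != b and np.isfinite(Ds[a, b])]
            le.append(sum(inv) / (m * (m - 1)))
        else:
            le.append(0.0)
    out["shortest_path_length"] = np.array(spl)
    out["global_efficiency"] = np.array(eg)
    out["clustering_coefficient"] = np.array(cl)
    out["local_efficiency"] = np.array(le)
    out["betweenness"] = oracle_betweenness(A, D)
    return out


def oracle_betweenness(A, D):
    """Count all shortest paths by exhaustive DFS over the BFS DAG."""
    n = A.shape[0]

    def all_paths(s, t):
        if not np.isfinite(D[s, t]) or s == t:
            return []
        paths, stack = [], [[s]]
        while stack:
            p = stack.pop()
            u = p[-1]
            if u == t:
                paths.append(p)
                continue
            for v in np.flatnonzero(A[u]):
                if D[s, v] == D[s, u] + 1 and D[s, v] + D[v, t] == D[s, t]:
                    stack.append(p + [int(v)])
        return paths

    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s >= t:
                continue
            paths = all_paths(s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def oracle_transitivity(A):
    n = A.shape[0]
    tri = sum(A[i, j] * A[j, k] * A[i, k]
              for i, j, k in itertools.combinations(range(n), 3))
    triples = sum(int(A[i].sum() * (A[i].sum() - 1) / 2) for i in range(n))
    return 3.0 * tri / triples if triples else np.nan


# ----------------------------------------------------------------- tests

class TestBinarize:
    def test_subthreshold_matrix_empty(self, rng):
        r = rng.uniform(-0.04, 0.04, (6, 6))
        r = (r + r.T) / 2
        z = np.arctanh(r)
        g = binarize(ConnectivityMatrix(z=z, roi_ids=list(range(1, 7))), 0.05)
        assert g.n_edges == 0 and g.density == 0.0

    def test_strong_matrix_complete(self):
        z = np.arctanh(np.full((5, 5), 0.9))
        np.fill_diagonal(z, 0)
        g = binarize(z, 0.3)
        assert g.density == 1.0

    def test_density_monotone_in_threshold(self, rng):
        for _ in range(100):
            r = rng.uniform(-0.9, 0.9, (10, 10))
            r = (r + r.T) / 2
            z = np.arctanh(r)
            d_low = binarize(z, 0.05).density
            d_high = binarize(z, 0.30).density
            assert d_low >= d_high

    def test_negative_correlations_never_edges(self):
        z = np.arctanh(np.array([[0.0, -0.9], [-0.9, 0.0]]))
        assert binarize(z, 0.05).n_edges == 0


class TestNodalMetrics:
    def test_complete_graph(self):
        g = graph_from_edges(4, itertools.combinations(range(4), 2))
        nm = nodal_metrics(g)
        assert (nm["degree"] == 3).all()
        assert np.allclose(nm["shortest_path_length"], 1.0)
        assert np.allclose(nm["global_efficiency"], 1.0)
        assert np.allclose(nm["clustering_coefficient"], 1.0)

    def test_path_graph_hand_count(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        nm = nodal_metrics(g)
        assert list(nm["degree"]) == [1, 2, 2, 1]
        assert nm["shortest_path_length"][0] == pytest.approx((1 + 2 + 3) / 3)

    def test_triangle_with_pendant(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (0, 2), (2, 3)])
        nm = nodal_metrics(g)
        assert np.allclose(nm["clustering_coefficient"], [1, 1, 1 / 3, 0])
        assert transitivity(g) == pytest.approx(0.6)

    def test_matches_brute_force_oracle_on_random_graphs(self, rng):
        """All nodal metrics + transitivity/assortativity vs enumeration on
        random graphs with up to 12 nodes (the acceptance suite runs the
        full 200-graph sweep)."""
        for trial in range(60):
            n = int(rng.integers(4, 13))
            p = float(rng.uniform(0.1, 0.9))
            A = (rng.random((n, n)) < p).astype(int)
            A = np.triu(A, 1)
            A = A + A.T
            g = BinaryGraph(adjacency=A)
            nm = nodal_metrics(g)
            oracle = oracle_nodal(A)
            for metric in NODAL_METRICS:
                assert np.allclose(nm[metric].to_numpy(), oracle[metric],
                                   atol=1e-9), (trial, metric)
            t_mine = transitivity(g)
            t_oracle = oracle_transitivity(A)
            if np.isnan(t_oracle):
                assert np.isnan(t_mine)
            else:
                assert t_mine == pytest.approx(t_oracle, abs=1e-9)
            if g.n_edges >= 2:
                a_nx = nx.degree_assortativity_coefficient(g.to_networkx())
                a_mine = assortativity(g)
                if np.isfinite(a_nx):
                    assert a_mine == pytest.approx(a_nx, abs=1e-6)

    def test_adding_edge_monotonicity(self, rng):
        """An extra edge never lowers a degree nor lengthens any path."""
        for _ in range(20):
            n = 8
            A = (rng.random((n, n)) < 0.3).astype(int)
            A = np.triu(A, 1); A = A + A.T
            g = BinaryGraph(adjacency=A)
            absent = [(i, j) for i in range(n) for j in range(i + 1, n)
                      if not A[i, j]]
            if not absent:
                continue
            i, j = absent[int(rng.integers(len(absent)))]
            A2 = A.copy(); A2[i, j] = A2[j, i] = 1
            g2 = BinaryGraph(adjacency=A2)
            assert (g2.degrees() >= g.degrees()).all()
            # characteristic path length is monotone when no new pairs
            # become reachable (it averages over reachable pairs only)
            if g.n_edges > 0 and nx.is_connected(g.to_networkx()):
                assert characteristic_path_length(g2) <= \
                    characteristic_path_length(g) + 1e-12


class TestGlobalMetrics:
    def test_complete_graph_values(self):
        g = graph_from_edges(4, itertools.combinations(range(4), 2))
        gm = global_metrics(g, n_null=5, seed=0)
        assert gm["transitivity"] == pytest.approx(1.0)
        assert gm["clustering_coefficient"] == pytest.approx(1.0)
        assert gm["shortest_path_length"] == pytest.approx(1.0)

    def test_star_graph_assortativity_minus_one(self):
        g = graph_from_edges(6, [(0, k) for k in range(1, 6)])
        assert assortativity(g) == pytest.approx(-1.0, abs=1e-12)

    def test_transitivity_one_iff_all_triples_closed(self):
        for n in range(3, 7):
            g = graph_from_edges(n, itertools.combinations(range(n), 2))
            assert transitivity(g) == pytest.approx(1.0)

    def test_sigma_identity_and_er_near_one(self, rng):
        """Erdos-Renyi graphs are their own null: sigma ~ 1."""
        sigmas = []
        for s in range(20):
            A = (np.random.default_rng(s).random((60, 60)) < 0.2).astype(int)
            A = np.triu(A, 1); A = A + A.T
            g = BinaryGraph(adjacency=A)
            gm = global_metrics(g, n_null=10, seed=s)
            assert gm["small_worldness"] == pytest.approx(
                gm["gamma"] / gm["lambda"], abs=1e-9)
            sigmas.append(gm["small_worldness"])
        assert 0.8 < np.mean(sigmas) < 1.2

    def test_edgeless_graph_undefined_metrics(self):
        g = BinaryGraph(adjacency=np.zeros((5, 5), dtype=int))
        gm = global_metrics(g, n_null=5, seed=0)
        for key in ("assortativity", "transitivity", "gamma", "lambda",
                    "small_worldness"):
            assert np.isnan(gm[key])


class TestRandomReference:
    def test_degree_sequence_preserved(self, rng):
        for s in range(10):
            A = (np.random.default_rng(s).random((15, 15)) < 0.3).astype(int)
            A = np.triu(A, 1); A = A + A.T
            g = BinaryGraph(adjacency=A)
            null = random_reference(g, seed=s)
            assert sorted(null.degrees()) == sorted(g.degrees())
            assert np.all(np.diag(null.adjacency) == 0)

    def test_triangle_returned_unchanged(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        null = random_reference(g, seed=0)
        assert np.array_equal(null.adjacency, g.adjacency)

    def test_lattice_ring_clustering_drops(self):
        """Ring lattice (R=50, k=4): rewired nulls always less clustered."""
        n, k = 50, 4
        A = np.zeros((n, n), dtype=int)
        for i in range(n):
            for d in range(1, k // 2 + 1):
                j = (i + d) % n
                A[i, j] = A[j, i] = 1
        g = BinaryGraph(adjacency=A)
        C = mean_clustering(g)
        for s in range(100):
            assert mean_clustering(random_reference(g, seed=s)) < C


class TestFeatureBlock:
    def test_counts_at_standard_parcellation(self, rng):
        """116 nodes x 6 thresholds: 66 NMglobal and 4176 NMnodal names."""
        r = rng.uniform(-0.4, 0.6, (116, 116))
        r = (r + r.T) / 2
        z = np.arctanh(np.clip(r, -0.95, 0.95))
        np.fill_diagonal(z, 0)
        cm = ConnectivityMatrix(z=z, roi_ids=list(range(1, 117)))
        block = network_feature_block(cm, n_null=2, seed=0)
        counts = block["subcategory"].value_counts()
        assert counts["NMglobal"] == 66
        assert counts["NMnodal"] == 4176

    def test_counts_at_toy_parcellation(self, rng):
        r = rng.uniform(-0.4, 0.6, (12, 12)); r = (r + r.T) / 2
        z = np.arctanh(r); np.fill_diagonal(z, 0)
        cm = ConnectivityMatrix(z=z, roi_ids=list(range(1, 13)))
        block = network_feature_block(cm, n_null=2, seed=0)
        assert (block["subcategory"] == "NMnodal").sum() == 12 * 6 * 6
        assert (block["subcategory"] == "NMglobal").sum() == 66

    def test_names_unique_and_stable(self, rng):
        r = rng.uniform(-0.4, 0.6, (8, 8)); r = (r + r.T) / 2
        z = np.arctanh(r); np.fill_diagonal(z, 0)
        cm = ConnectivityMatrix(z=z, roi_ids=list(range(1, 9)))
        b1 = network_feature_block(cm, n_null=2, seed=0)
        b2 = network_feature_block(cm, n_null=2, seed=0)
        assert not b1.index.duplicated().any()
        assert list(b1.index) == list(b2.index)
        assert np.allclose(b1["value"].to_numpy(), b2["value"].to_numpy(),
                           equal_nan=True)
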