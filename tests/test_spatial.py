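"""Geometric graph construction and the mean clustering coefficient.

Oracles: an O(n²) pairwise-distance edge oracle, dense-matrix triangle
counting, and networkx's clustering implementation as an independent
cross-check.
"""

import math

import numpy as np
import pytest

import nftburden as nb
from nftburden.errors import DomainError


def brute_force_mean_cc(points, r):
    """Independent O(n³) oracle: full distance matrix, explicit triple loop
    via matrix powers."""
    pts = np.asarray(points, float)
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    a = (d < r).astype(float)
    np.fill_diagonal(a, 0.0)
    deg = a.sum(1)
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1)
    cc = np.where(denom > 0, 2 * tri / np.where(denom > 0, denom, 1), 0.0)
    return cc.mean()


class TestGraphConstruction:
    def test_exact_distance_is_not_an_edge(self):
        g = nb.build_geometric_graph([(0.0, 0.0), (1.0, 0.0)], r_px=1.0)
        assert g.n_edges == 0
        g = nb.build_geometric_graph([(0.0, 0.0), (1.0, 0.0)], r_px=1.0 + 1e-9)
        assert g.n_edges == 1

    def test_tiny_radius_gives_empty_graph(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        g = nb.build_geometric_graph(pts, r_px=1e-12)
        assert g.n_edges == 0

    def test_edge_set_matches_pairwise_oracle(self, rng):
        pts = rng.uniform(0, 1000, (200, 2))
        r = 120.0
        g = nb.build_geometric_graph(pts, r)
        got = {tuple(sorted(e)) for e in g.edges.tolist()}
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        expect = {
            (i, j) for i in range(len(pts)) for j in range(i + 1, len(pts))
            if d[i, j] < r
        }
        assert got == expect

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(DomainError):
            nb.build_geometric_graph([(0, 0), (np.inf, 1)], r_px=1.0)


class TestLocalClustering:
    def test_complete_triangle(self):
        g = nb.build_geometric_graph([(0, 0), (1, 0), (0.5, 0.8)], r_px=2.0)
        assert all(nb.local_clustering(g, i) == 1.0 for i in range(3))

    def test_open_triad_midpoint(self):
        g = nb.build_geometric_graph([(0, 0), (1, 0), (2, 0)], r_px=1.5)
        assert nb.local_clustering(g, 1) == 0.0
        assert nb.local_clustering(g, 0) == 0.0  # degree 1 -> 0 by convention

    def test_invalid_node_rejected(self):
        g = nb.build_geometric_graph([(0, 0), (1, 0)], r_px=2.0)
        with pytest.raises(DomainError):
            nb.local_clustering(g, 5)

    def test_matches_networkx(self, rng):
        networkx = pytest.importorskip("networkx")
        pts = rng.uniform(0, 500, (80, 2))
        r = 90.0
        g = nb.build_geometric_graph(pts, r)
        G = networkx.Graph()
        G.add_nodes_from(range(g.n_nodes))
        G.add_edges_from(map(tuple, g.edges.tolist()))
        expect = networkx.clustering(G)
        for i in range(g.n_nodes):
            assert nb.local_clustering(g, i) == pytest.approx(expect[i], abs=1e-12)


class TestMeanClusteringCoefficient:
    def test_equilateral_triangle(self):
        s = 10.0
        pts = [(0, 0), (s, 0), (s / 2, s * math.sqrt(3) / 2)]
        assert nb.mean_clustering_coefficient(pts, r_px=s * 1.01) == 1.0

    def test_square_four_cycle_is_triangle_free(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert nb.mean_clustering_coefficient(pts, r_px=1.2) == 0.0

    def test_fewer_than_three_points_is_nan(self):
        assert math.isnan(nb.mean_clustering_coefficient([(0, 0), (1, 1)], 10.0))

    def test_matches_brute_force_on_clustered_pattern(self, regions):
        pts = nb.simulate_thomas(0.2, 15.0, 300.0, regions[1], seed=5)[:300]
        for r in (200.0, 800.0, 2500.0):
            assert nb.mean_clustering_coefficient(pts, r) == pytest.approx(
                brute_force_mean_cc(pts, r), abs=1e-12
            )

    def test_matches_networkx_average_clustering(self, rng):
        networkx = pytest.importorskip("networkx")
        pts = rng.uniform(0, 400, (60, 2))
        r = 80.0
        g = nb.build_geometric_graph(pts, r)
        G = networkx.Graph()
        G.add_nodes_from(range(g.n_nodes))
        G.add_edges_from(map(tuple, g.edges.tolist()))
        assert nb.mean_clustering_coefficient(pts, r) == pytest.approx(
            networkx.average_clustering(G, count_zeros=True), abs=1e-12
        )

    def test_rigid_transform_invariance(self, rng):
        pts = rng.uniform(0, 1000, (120, 2))
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = pts @ rot.T + np.array([5000.0, -3000.0])
        for r in (50.0, 150.0, 400.0):
            assert nb.mean_clustering_coefficient(moved, r) == pytest.approx(
                nb.mean_clustering_coefficient(pts, r), abs=1e-9
            )

    def test_limits(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        diam = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)).max()
        assert nb.mean_clustering_coefficient(pts, diam * 1.01) == 1.0
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert nb.mean_clustering_coefficient(pts, d.min() * 0.99) == 0.0

    def test_excluding_low_degree_nodes_convention(self):
        # triangle plus a far-away isolated point
        pts = [(0, 0), (1, 0), (0.5, 0.8), (100, 100)]
        inc = nb.mean_clustering_coefficient(pts, 2.0, include_low_degree=True)
        exc = nb.mean_clustering_coefficient(pts, 2.0, include_low_degree=False)
        assert inc == pytest.approx(0.75)
        assert exc == pytest.approx(1.0)


class TestSweep:
    def test_default_grid_has_fifty_radii(self):
        assert len(nb.sweep_grid()) == 50
        assert nb.sweep_grid()[0] == 100.0
        assert nb.sweep_grid()[-1] == 5000.0

    def test_tight_cluster_is_one_everywhere(self, rng):
        pts = rng.uniform(0, 50, (10, 2))
        sw = nb.clustering_sweep(pts)
        assert np.all(sw.mean_cc == 1.0)

    def test_self_consistency_with_standalone_call(self, regions):
        pts = nb.simulate_thomas(0.1, 20.0, 400.0, regions[1], seed=3)
        sw = nb.clustering_sweep(pts)
        assert sw.at_r(800.0) == nb.mean_clustering_coefficient(pts, 800.0)
        assert sw.n_nfts == len(pts)

    def test_undefined_propagates_as_missing(self):
        sw = nb.clustering_sweep(np.array([[0.0, 0.0], [5.0, 5.0]]))
        assert np.all(np.isnan(sw.mean_cc))
        assert sw.n_nfts == 2

    def test_invalid_grid_rejected(self):
        with pytest.raises(DomainError):
            nb.clustering_sweep(np.zeros((5, 2)), r_start_px=500, r_stop_px=100)

    def test_sweep_table_columns(self, tmp_path, rng):
        pts = rng.uniform(0, 2000, (20, 2))
        sw = nb.clustering_sweep(pts, subject_id="s1")
        nb.write_sweep_table([sw], tmp_path / "sweep.csv", nb.DEFAULT_PIXEL_SIZE_UM)
        import pandas as pd

        back = pd.read_csv(tmp_path / "sweep.csv")
        assert list(back.columns) == ["subject_id", "r_px", "r_um", "mean_cc", "n_nfts"]
        assert back.r_um.iloc[0] == pytest.approx(50.66)

    def test_values_bounded(self, regions):
        pts = nb.simulate_csr(2.0, regions[0], seed=9)
        sw = nb.clustering_sweep(pts)
        ok = np.isfinite(sw.mean_cc)
        assert np.all(sw.mean_cc[ok] >= 0) and np.all(sw.mean_cc[ok] <= 1)
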