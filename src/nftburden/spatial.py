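"""Geometric-graph spatial clustering of NFT centroids.

The degree of spatial clustering of tangles on a slide is summarised by the
mean clustering coefficient of a random-geometric graph: every NFT centroid
is a node, and an edge joins two nodes iff the Euclidean distance between
them is strictly less than a radius threshold ``r`` (in level-0 pixels).
The local clustering coefficient of node *i* is

    C_i = 2 T_i / (k_i (k_i - 1))

where ``k_i`` is the degree and ``T_i`` the number of triangles through
*i*; the slide-level statistic is the arithmetic mean of ``C_i`` over all
nodes.  Because there is no canonical inter-NFT distance scale, the metric
is computed over a sweep of radii (default 100–5000 px in 100 px steps);
the total NFT count is carried alongside the sweep as a nuisance covariate
for downstream regressions.

Neighbour search uses a kd-tree fixed-radius query (exact, not
approximate).  Candidate pairs returned at distance <= r are re-checked
with an exact squared-distance comparison so the strict ``< r`` edge rule
holds; ties at exactly r are resolved as non-edges.

Conventions (configurable where noted):

* nodes of degree < 2 contribute a clustering coefficient of 0 to the mean
  (the dominant convention; ``include_low_degree=False`` excludes them);
* point sets with fewer than 3 points have no defined mean clustering
  coefficient — the functions return NaN, which the sweep propagates as a
  missing value, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .burden import px_to_micron
from .errors import DomainError

DEFAULT_R_START_PX = 100.0
DEFAULT_R_STOP_PX = 5000.0
DEFAULT_R_STEP_PX = 100.0

#: Largest node count for which triangle counting goes through a dense
#: boolean adjacency matrix (O(n^2) memory); larger graphs fall back to
#: neighbour-set intersection.
_DENSE_LIMIT = 2048


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError(f"points must be an (n, 2) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise DomainError("point coordinates must be finite")
    return pts


def _strict_pairs(tree: cKDTree, pts: np.ndarray, r_px: float) -> np.ndarray:
    """Index pairs (i < j) at Euclidean distance strictly below r_px."""
    pairs = tree.query_pairs(r_px, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    diff = pts[pairs[:, 0]] - pts[pairs[:, 1]]
    keep = (diff * diff).sum(axis=1) < r_px * r_px
    return pairs[keep]


@dataclass
class GeometricGraph:
    """Undirected radius graph over a fixed point set.

    ``edges`` holds each unordered pair once as (i, j) with i < j.
    """

    n_nodes: int
    r_px: float
    edges: np.ndarray

    _adjacency: Optional[list[set[int]]] = field(default=None, repr=False, compare=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> list[set[int]]:
        if self._adjacency is None:
            adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
            for i, j in self.edges:
                adj[i].add(int(j))
                adj[j].add(int(i))
            self._adjacency = adj
        return self._adjacency

    def degree(self, node: int) -> int:
        return len(self.adjacency()[node])


def build_geometric_graph(points, r_px: float) -> GeometricGraph:
    """Build the radius graph: edge (i, j) iff ||p_i - p_j|| < r_px."""
    pts = _as_points(points)
    if len(pts) < 1:
        raise DomainError("need at least one point")
    if not r_px > 0:
        raise DomainError("r_px must be > 0")
    tree = cKDTree(pts)
    return GeometricGraph(n_nodes=len(pts), r_px=float(r_px),
                          edges=_strict_pairs(tree, pts, r_px))


def local_clustering(graph: GeometricGraph, node: int) -> float:
    """Fraction of a node's neighbour pairs that are themselves connected.

    Nodes of degree < 2 return 0 by convention.
    """
    if not (0 <= node < graph.n_nodes):
        raise DomainError(f"node index {node} out of range [0, {graph.n_nodes})")
    adj = graph.adjacency()
    nbrs = adj[node]
    k = len(nbrs)
    if k < 2:
        return 0.0
    triangles = sum(len(adj[m] & nbrs) for m in nbrs) // 2
    return 2.0 * triangles / (k * (k - 1))


def _mean_cc(tree: cKDTree, pts: np.ndarray, r_px: float,
             include_low_degree: bool) -> float:
    n = len(pts)
    if n < 3:
        return float("nan")
    pairs = _strict_pairs(tree, pts, r_px)
    deg = np.zeros(n, dtype=np.int64)
    if len(pairs):
        np.add.at(deg, pairs[:, 0], 1)
        np.add.at(deg, pairs[:, 1], 1)
    triangles = np.zeros(n)
    if len(pairs):
        if n <= _DENSE_LIMIT:
            A = np.zeros((n, n), dtype=np.float32)
            A[pairs[:, 0], pairs[:, 1]] = 1.0
            A[pairs[:, 1], pairs[:, 0]] = 1.0
            triangles = (A * (A @ A)).sum(axis=1) / 2.0
        else:
            adj: list[set[int]] = [set() for _ in range(n)]
            for i, j in pairs:
                adj[i].add(int(j))
                adj[j].add(int(i))
            triangles = np.array(
                [sum(len(adj[m] & nbrs) for m in nbrs) / 2.0 for nbrs in adj]
            )
    denom = deg.astype(float) * (deg - 1)
    cc = np.divide(2.0 * triangles, denom, out=np.zeros(n), where=denom > 0)
    if include_low_degree:
        return float(cc.mean())
    eligible = deg >= 2
    if not eligible.any():
        return float("nan")
    return float(cc[eligible].mean())


def mean_clustering_coefficient(points, r_px: float,
                                include_low_degree: bool = True) -> float:
    """Mean local clustering coefficient of the radius graph over ``points``.

    Returns NaN for point sets of fewer than 3 points (the statistic is
    undefined there, which is distinct from a measured value of 0).
    """
    pts = _as_points(points)
    if not r_px > 0:
        raise DomainError("r_px must be > 0")
    if len(pts) < 3:
        return float("nan")
    return _mean_cc(cKDTree(pts), pts, r_px, include_low_degree)


@dataclass
class ClusteringSweep:
    """Mean clustering coefficient as a function of the radius threshold."""

    subject_id: str
    r_values_px: np.ndarray
    mean_cc: np.ndarray  # NaN where undefined (fewer than 3 NFTs)
    n_nfts: int

    def __post_init__(self) -> None:
        self.r_values_px = np.asarray(self.r_values_px, dtype=float)
        self.mean_cc = np.asarray(self.mean_cc, dtype=float)
        if len(self.r_values_px) != len(self.mean_cc):
            raise DomainError("r grid and mean_cc lengths differ")

    def at_r(self, r_px: float) -> float:
        idx = np.nonzero(np.isclose(self.r_values_px, r_px))[0]
        if len(idx) == 0:
            raise KeyError(f"r={r_px} not on the sweep grid")
        return float(self.mean_cc[idx[0]])


def sweep_grid(r_start_px: float = DEFAULT_R_START_PX,
               r_stop_px: float = DEFAULT_R_STOP_PX,
               r_step_px: float = DEFAULT_R_STEP_PX) -> np.ndarray:
    """Inclusive arithmetic radius grid (default 100, 200, ..., 5000 px)."""
    if not (0 < r_start_px <= r_stop_px) or not r_step_px > 0:
        raise DomainError("require 0 < r_start <= r_stop and r_step > 0")
    n_steps = int(np.floor((r_stop_px - r_start_px) / r_step_px + 1e-9))
    return r_start_px + r_step_px * np.arange(n_steps + 1)


def clustering_sweep(points,
                     r_start_px: float = DEFAULT_R_START_PX,
                     r_stop_px: float = DEFAULT_R_STOP_PX,
                     r_step_px: float = DEFAULT_R_STEP_PX,
                     subject_id: str = "",
                     include_low_degree: bool = True) -> ClusteringSweep:
    """Mean clustering coefficient at every radius of the grid.

    Point sets with fewer than 3 points yield NaN at every radius.
    """
    pts = _as_points(points)
    rs = sweep_grid(r_start_px, r_stop_px, r_step_px)
    if len(pts) < 3:
        cc = np.full(len(rs), np.nan)
    else:
        tree = cKDTree(pts)
        cc = np.array([_mean_cc(tree, pts, r, include_low_degree) for r in rs])
    return ClusteringSweep(subject_id=subject_id, r_values_px=rs,
                           mean_cc=cc, n_nfts=len(pts))


def sweeps_to_frame(sweeps: Sequence[ClusteringSweep],
                    pixel_size_um: float) -> pd.DataFrame:
    """Long-format table: subject_id, r_px, r_um, mean_cc, n_nfts."""
    rows = []
    for sw in sweeps:
        for r, cc in zip(sw.r_values_px, sw.mean_cc):
            rows.append(
                {
                    "subject_id": sw.subject_id,
                    "r_px": r,
                    "r_um": px_to_micron(r, pixel_size_um),
                    "mean_cc": cc,
                    "n_nfts": sw.n_nfts,
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "r_px", "r_um", "mean_cc", "n_nfts"])


def write_sweep_table(sweeps: Sequence[ClusteringSweep], path: str | Path,
                      pixel_size_um: float) -> None:
    sweeps_to_frame(sweeps, pixel_size_um).to_csv(Path(path), index=False)
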