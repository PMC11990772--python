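"""Spatial neighbor graphs from spot coordinates.

Adjacency is built with an alpha-complex style rule: an edge is kept when it
is a Delaunay edge of the coordinates and its Euclidean length is at most
``2 r``, where the radius ``r`` is estimated as the global mean, over spots,
of each spot's mean distance to its ``k`` nearest neighbors. For a Gabriel
edge the nearest point of the shared Voronoi facet is the midpoint at
distance L/2, so ``L <= 2r`` is exactly the alpha condition; non-Gabriel
Delaunay edges are slightly over-included. This geometric construction
adapts to non-uniform spot densities better than a plain kNN graph.

Degenerate inputs (fewer than three points, collinear layouts) fall back to
a symmetrized kNN graph with the same ``k``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError
from sklearn.neighbors import NearestNeighbors

from .errors import InsufficientPointsError

logger = logging.getLogger(__name__)


@dataclass
class SpatialGraph:
    """Spot adjacency structure for one slice."""

    n_spots: int
    edges: np.ndarray  # (E, 2) int array, i < j, each unordered pair once
    adjacency: sp.csr_matrix  # n x n symmetric 0/1, zero diagonal
    radius: float
    k_neighbors: int

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_lengths(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        d = coords[self.edges[:, 0]] - coords[self.edges[:, 1]]
        return np.sqrt((d * d).sum(axis=1))

    def export_edge_list(self, path, coords: np.ndarray | None = None):
        """Write a TSV edge list (i, j[, length]) for inspection."""
        import pandas as pd

        df = pd.DataFrame(self.edges, columns=["i", "j"])
        if coords is not None:
            df["length"] = self.edge_lengths(coords)
        df.to_csv(path, sep="\t", index=False)


def estimate_radius(coords: np.ndarray, k: int) -> float:
    """Global neighborhood radius: mean over spots of the mean Euclidean
    distance to each spot's ``k`` nearest neighbors (self excluded)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise InsufficientPointsError(
            f"need more than k={k} points to estimate the radius (got {n})"
        )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    dist = dist[:, 1:]  # drop self
    if np.any(dist == 0):
        warnings.warn(
            "duplicate coordinates collapse nearest-neighbor distances to 0",
            stacklevel=2,
        )
    return float(dist.mean())


def _knn_edges(coords: np.ndarray, k: int) -> np.ndarray:
    n = coords.shape[0]
    k_eff = min(k, n - 1)
    if k_eff < 1:
        return np.empty((0, 2), dtype=int)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    pairs = set()
    for i in range(n):
        for j in idx[i, 1:]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    return np.array(sorted(pairs), dtype=int) if pairs else np.empty((0, 2), dtype=int)


def _delaunay_edges(coords: np.ndarray) -> np.ndarray:
    tri = Delaunay(coords)
    pairs = set()
    for simplex in tri.simplices:
        a, b, c = int(simplex[0]), int(simplex[1]), int(simplex[2])
        for i, j in ((a, b), (a, c), (b, c)):
            pairs.add((min(i, j), max(i, j)))
    return np.array(sorted(pairs), dtype=int)


def _adjacency_from_edges(edges: np.ndarray, n: int) -> sp.csr_matrix:
    if edges.shape[0] == 0:
        return sp.csr_matrix((n, n))
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    data = np.ones(rows.shape[0])
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def build_spatial_graph(coords: np.ndarray, k: int = 6) -> SpatialGraph:
    """Build the alpha-style spatial graph for one slice.

    Delaunay edges whose length is at most ``2 r`` (closed threshold) are
    kept, with ``r`` from :func:`estimate_radius`. Degenerate geometry falls
    back to a symmetrized kNN graph.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise InsufficientPointsError("need at least 2 spots to build a graph")
    r = estimate_radius(coords, min(k, n - 1))
    try:
        if n < 3:
            raise QhullError("fewer than 3 points")
        edges = _delaunay_edges(coords)
    except QhullError:
        warnings.warn(
            "degenerate coordinate geometry; falling back to a symmetrized "
            f"{k}-nearest-neighbor graph",
            stacklevel=2,
        )
        edges = _knn_edges(coords, k)
        adjacency = _adjacency_from_edges(edges, n)
        return SpatialGraph(n, edges, adjacency, r, k)
    d = coords[edges[:, 0]] - coords[edges[:, 1]]
    lengths = np.sqrt((d * d).sum(axis=1))
    edges = edges[lengths <= 2.0 * r]
    adjacency = _adjacency_from_edges(edges, n)
    logger.debug("spatial graph: n=%d edges=%d r=%.4g", n, edges.shape[0], r)
    return SpatialGraph(n, edges, adjacency, r, k)


def normalize_adjacency(graph: SpatialGraph | sp.spmatrix) -> sp.csr_matrix:
    """Symmetric normalization with self-loops: D^{-1/2} (A + I) D^{-1/2}.

    Rows of isolated nodes reduce to a self-loop of weight 1. This is the
    propagation operator used by the graph-convolutional encoder.
    """
    A = graph.adjacency if isinstance(graph, SpatialGraph) else sp.csr_matrix(graph)
    n = A.shape[0]
    A_hat = (A + sp.identity(n, format="csr", dtype=float)).tocsr()
    deg = np.asarray(A_hat.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return (D @ A_hat @ D).tocsr()
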