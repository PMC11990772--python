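import numpy as np
import pytest

from tacos.community import CommunityPartition
from tacos.slice_io import Slice
from tacos.spatial_graph import SpatialGraph, _adjacency_from_edges


def graph_from_edges(edges, n) -> SpatialGraph:
    """Build a SpatialGraph directly from an edge list (test helper)."""
    edges = np.array(sorted((min(i, j), max(i, j)) for i, j in edges), dtype=int)
    edges = edges.reshape(-1, 2)
    return SpatialGraph(
        n_spots=n,
        edges=edges,
        adjacency=_adjacency_from_edges(edges, n),
        radius=1.0,
        k_neighbors=1,
    )


@pytest.fixture
def two_triangles_bridge():
    """Two triangles {0,1,2} and {3,4,5} joined by the bridge edge (2,3)."""
    edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
    graph = graph_from_edges(edges, 6)
    partition = CommunityPartition.from_assignment([0, 0, 0, 1, 1, 1], graph)
    return graph, partition


@pytest.fixture
def small_slice():
    rng = np.random.default_rng(0)
    n, m = 12, 7
    return Slice(
        spot_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(m)],
        X=rng.poisson(3.0, size=(n, m)).astype(float),
        coords=rng.uniform(0, 10, size=(n, 2)),
        slice_id="fixture",
    )


def finite_difference_grad(f, x, eps=1e-5):
    """Central finite-difference gradient of scalar f at ndarray x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
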