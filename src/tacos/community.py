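"""Community detection on the spatial graph and per-community strength.

Communities are found with Leiden modularity optimization on the spatial
neighbor graph, using edge weights given by the cosine similarity (clipped
at zero) between the endpoints' feature vectors — either the normalized
expression profile or a low-dimensional embedding. The strength of community
c is its modularity contribution

    S_c = E_c / |E|  -  (sum_{v in c} d_v)^2 / (4 |E|^2),

with E_c the number of intra-community edges and d_v the node degree, so the
strengths sum exactly to the Newman modularity of the partition. Strengths
may be negative for weak communities and are deliberately not clipped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np

from .slice_io import LOG_NORMALIZED, Slice
from .spatial_graph import SpatialGraph


@dataclass
class CommunityPartition:
    """Community assignment plus indicator matrix and strength scores."""

    assignment: np.ndarray  # (n,) int community index in 0..C-1
    H: np.ndarray  # (n, C) 0/1 indicator
    strengths: np.ndarray  # (C,)
    n_communities: int

    @classmethod
    def from_assignment(cls, assignment, graph: SpatialGraph | None = None):
        assignment = np.asarray(assignment, dtype=int)
        C = int(assignment.max()) + 1 if assignment.size else 0
        H = np.zeros((assignment.size, C))
        H[np.arange(assignment.size), assignment] = 1.0
        strengths = (
            community_strength_from_assignment(assignment, graph)
            if graph is not None
            else np.zeros(C)
        )
        return cls(assignment, H, strengths, C)

    def export(self, spot_ids, tsv_path, strengths_json_path=None):
        import pandas as pd

        pd.DataFrame({"spot_id": list(spot_ids), "community": self.assignment}).to_csv(
            tsv_path, sep="\t", index=False
        )
        if strengths_json_path is not None:
            with open(strengths_json_path, "w") as fh:
                json.dump([float(s) for s in self.strengths], fh)


def _cosine_edge_weights(features: np.ndarray, edges: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    norms = np.linalg.norm(features, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    fn = features / norms[:, None]
    w = np.einsum("ij,ij->i", fn[edges[:, 0]], fn[edges[:, 1]])
    return np.clip(w, 0.0, None)


def detect_communities(
    slice_: Slice,
    graph: SpatialGraph,
    mode: str = "expression",
    embedding: np.ndarray | None = None,
    resolution: float = 1.0,
    seed: int = 0,
) -> CommunityPartition:
    """Leiden communities on the spatial graph with feature-derived weights.

    ``mode="expression"`` weights edges by the cosine similarity of the
    log-normalized expression of their endpoints; ``mode="embedding"`` uses
    the provided embedding instead. Deterministic for a fixed seed. A graph
    without edges yields a single community with a warning.
    """
    if mode == "expression":
        if slice_.processing != LOG_NORMALIZED:
            raise ValueError("expression-mode community detection needs a log_normalized slice")
        features = slice_.X
    elif mode == "embedding":
        if embedding is None:
            raise ValueError("mode='embedding' requires an embedding matrix")
        features = np.asarray(embedding)
        if features.shape[0] != graph.n_spots:
            raise ValueError("embedding row count does not match graph")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n = graph.n_spots
    if graph.n_edges == 0:
        warnings.warn("graph has no edges; assigning all spots to one community", stacklevel=2)
        return CommunityPartition.from_assignment(np.zeros(n, dtype=int), None)

    weights = _cosine_edge_weights(features, graph.edges)
    g = igraph.Graph(n=n, edges=[tuple(e) for e in graph.edges.tolist()])
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=list(map(float, weights)),
        resolution_parameter=float(resolution),
        seed=int(seed),
    )
    assignment = np.asarray(part.membership, dtype=int)
    return CommunityPartition.from_assignment(assignment, graph)


def community_strength_from_assignment(
    assignment: np.ndarray, graph: SpatialGraph
) -> np.ndarray:
    assignment = np.asarray(assignment, dtype=int)
    E = graph.n_edges
    if E == 0:
        raise ZeroDivisionError(
            "community strength is undefined on a graph with no edges; "
            "check the spatial graph construction (radius / k)"
        )
    C = int(assignment.max()) + 1
    ci = assignment[graph.edges[:, 0]]
    cj = assignment[graph.edges[:, 1]]
    intra = np.zeros(C)
    np.add.at(intra, ci[ci == cj], 1.0)
    deg = np.asarray(graph.adjacency.sum(axis=1)).ravel()
    deg_sum = np.zeros(C)
    np.add.at(deg_sum, assignment, deg)
    return intra / E - deg_sum**2 / (4.0 * E**2)


def community_strength(partition: CommunityPartition, graph: SpatialGraph) -> np.ndarray:
    """Per-community strengths S_c; their sum is the partition modularity."""
    if partition.assignment.shape[0] != graph.n_spots:
        raise ValueError("partition does not cover the graph's spots")
    return community_strength_from_assignment(partition.assignment, graph)
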