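"""Augmented graph views for contrastive training.

Two augmentation policies are provided. The community-aware policy
("communal attribute voting" and "communal edge dropping") masks gene
features and drops edges with probabilities weighted by community strength:
genes loading strongly on strong communities are more likely to be masked,
and inter-community edges are much more likely to be dropped than
intra-community ones, so each view preserves community cores while
perturbing the periphery. The uniform-random policy used in the pretraining
stage masks gene columns and drops edges with flat probabilities.

Raw weights are min-max normalized to [0, 1]; a vector with all-equal
entries maps to a constant 0.5 so that the Bernoulli draws stay informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .community import CommunityPartition
from .spatial_graph import SpatialGraph, _adjacency_from_edges


@dataclass
class AugmentConfig:
    """Augmentation hyperparameters (probabilities all in [0, 1])."""

    p_attr_1: float = 0.3
    p_attr_2: float = 0.4
    p_edge_1: float = 0.9
    p_edge_2: float = 0.9
    edge_keep_floor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("p_attr_1", "p_attr_2", "p_edge_1", "p_edge_2", "edge_keep_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class AugmentedView:
    """A masked feature matrix / masked adjacency pair."""

    X_masked: np.ndarray  # (n, m)
    adjacency_masked: sp.csr_matrix  # (n, n) 0/1 symmetric, subset of input
    attr_mask: np.ndarray  # (n, m) 0/1 keep mask (constant within columns)
    edge_mask: np.ndarray  # (E,) 0/1 keep indicator per input edge


def minmax_norm(x: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; all-equal input maps to constant 0.5."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def attribute_mask_weights(X: np.ndarray, partition: CommunityPartition) -> np.ndarray:
    """Per-gene masking weight w = Norm(|X^T H S|).

    Genes with large absolute community-strength-weighted loadings get
    weights near 1 (most likely to be masked).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != partition.H.shape[0]:
        raise ValueError("X rows do not match partition")
    scores = np.abs(X.T @ (partition.H @ partition.strengths))
    return minmax_norm(scores)


def edge_mask_weights(graph: SpatialGraph, partition: CommunityPartition) -> np.ndarray:
    """Per-edge keep weight from community strengths.

    Intra-community edges get the shared community's strength; edges between
    communities get minus the sum of both endpoint strengths, so after
    min-max normalization inter-community edges sit near 0 (likely dropped)
    and edges inside strong communities near 1 (likely kept).
    """
    if graph.n_edges == 0:
        return np.empty(0)
    b = partition.H @ partition.strengths  # per-node strength of own community
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    intra = partition.assignment[i] == partition.assignment[j]
    raw = np.where(intra, b[i], -(b[i] + b[j]))
    return minmax_norm(raw)


def _mask_adjacency(graph: SpatialGraph, keep: np.ndarray) -> sp.csr_matrix:
    kept_edges = graph.edges[keep.astype(bool)]
    return _adjacency_from_edges(kept_edges, graph.n_spots)


def sample_view(
    X: np.ndarray,
    graph: SpatialGraph,
    partition: CommunityPartition,
    p_attr: float,
    p_edge: float,
    rng: np.random.Generator,
    edge_keep_floor: float = 0.0,
    attr_weights: np.ndarray | None = None,
    edge_weights: np.ndarray | None = None,
) -> AugmentedView:
    """Draw one community-aware augmented view.

    Gene column g is kept with probability ``1 - w_g * p_attr`` (the mask is
    broadcast over spots); edge e is kept with probability ``w_e * p_edge``
    (optionally floored). Probabilities are clipped into [0, 1]. Precomputed
    weight vectors may be passed to avoid recomputation inside training
    loops.
    """
    X = np.asarray(X)
    if not (0.0 <= p_attr <= 1.0 and 0.0 <= p_edge <= 1.0):
        raise ValueError("p_attr and p_edge must be in [0, 1]")
    w_attr = attribute_mask_weights(X, partition) if attr_weights is None else attr_weights
    keep_p_gene = np.clip(1.0 - w_attr * p_attr, 0.0, 1.0)
    col_keep = (rng.random(X.shape[1]) < keep_p_gene).astype(X.dtype)
    attr_mask = np.broadcast_to(col_keep, X.shape)
    X_masked = X * col_keep

    w_edge = edge_mask_weights(graph, partition) if edge_weights is None else edge_weights
    keep_p_edge = np.clip(np.maximum(w_edge * p_edge, edge_keep_floor), 0.0, 1.0)
    edge_keep = (rng.random(graph.n_edges) < keep_p_edge).astype(np.int8)
    return AugmentedView(X_masked, _mask_adjacency(graph, edge_keep), attr_mask, edge_keep)


def random_view(
    X: np.ndarray,
    graph: SpatialGraph,
    p_attr: float,
    p_edge_drop: float,
    rng: np.random.Generator,
) -> AugmentedView:
    """Uniform-random perturbation: each gene column masked with probability
    ``p_attr``, each edge dropped with probability ``p_edge_drop``."""
    X = np.asarray(X)
    if not (0.0 <= p_attr <= 1.0 and 0.0 <= p_edge_drop <= 1.0):
        raise ValueError("probabilities must be in [0, 1]")
    col_keep = (rng.random(X.shape[1]) >= p_attr).astype(X.dtype)
    attr_mask = np.broadcast_to(col_keep, X.shape)
    X_masked = X * col_keep
    edge_keep = (rng.random(graph.n_edges) >= p_edge_drop).astype(np.int8)
    return AugmentedView(X_masked, _mask_adjacency(graph, edge_keep), attr_mask, edge_keep)
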