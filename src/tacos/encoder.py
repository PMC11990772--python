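"""Two-layer graph-convolutional encoder and contrastive / spatial losses.

The encoder computes

    Z = A_hat . PReLU(A_hat . X . W1 + b1) . W2 + b2

with A_hat the symmetrically normalized adjacency (self-loops included), W1
mapping the gene dimension m to 2h and W2 reducing to the embedding
dimension h (default 50).

Training uses an InfoNCE objective between two augmented views: for spot i,
the positive is the same spot in the other view and the negatives are every
other spot in both views, with cosine similarities scaled by a temperature
tau. The community-enhanced variant adds a bonus gamma * (H_i + H_j) . S to
every pairwise similarity, so pairs inside strong communities are treated as
softer negatives; gamma follows the ramp schedule
min(max(0, k - k0), gamma_max) over epochs. The loss is symmetrized over the
two view directions.

A spatial regularizer encourages embedding distances to decrease with
spatial proximity: L_within = sum_ij D^s_ij (1 - D^Z_ij) / n^2 with both
distance matrices min-max normalized over the evaluated pairs. For large
slices a seeded random pair subsample replaces the full double sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

from ._autodiff import Tensor, as_tensor, prelu, spmm, take_rows
from .augmentation import AugmentedView
from .community import CommunityPartition
from .spatial_graph import normalize_adjacency

_EPS = 1e-8


@dataclass
class LossConfig:
    """Loss hyperparameters.

    tau : similarity temperature (> 0).
    gamma_k0, gamma_max : ramp schedule of the community bonus.
    alpha, beta : weights of the spatial and cross-slice terms in the total
        objective.
    theta : triplet margin.
    """

    tau: float = 0.5
    gamma_k0: int = 0
    gamma_max: float = 1.0
    alpha: float = 0.1
    beta: float = 1.0
    theta: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.gamma_max < 0 or self.theta < 0:
            raise ValueError("gamma_max and theta must be nonnegative")


class GCNEncoder:
    """Two-layer GCN: m -> 2h (PReLU) -> h."""

    def __init__(self, n_genes: int, h: int = 50, seed: int = 0, dtype=np.float32):
        if h < 2:
            raise ValueError("embedding dimension h must be >= 2")
        rng = np.random.default_rng(seed)
        self.n_genes = int(n_genes)
        self.h = int(h)
        m, h2 = self.n_genes, 2 * self.h

        def glorot(fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)

        self.W1 = Tensor(glorot(m, h2), requires_grad=True)
        self.b1 = Tensor(np.zeros(h2, dtype=dtype), requires_grad=True)
        self.slope = Tensor(np.asarray(0.25, dtype=dtype), requires_grad=True)
        self.W2 = Tensor(glorot(h2, self.h), requires_grad=True)
        self.b2 = Tensor(np.zeros(self.h, dtype=dtype), requires_grad=True)

    def parameters(self) -> list:
        return [self.W1, self.b1, self.slope, self.W2, self.b2]

    def forward(self, X: np.ndarray, A_norm: sp.spmatrix) -> Tensor:
        """Propagate features through the two GCN layers.

        ``A_norm`` must already be the normalized operator (see
        :func:`tacos.spatial_graph.normalize_adjacency`).
        """
        if X.shape[1] != self.n_genes:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match encoder ({self.n_genes})"
            )
        AX = A_norm @ np.asarray(X, dtype=self.W1.dtype)  # constant
        H1 = prelu(as_tensor(AX) @ self.W1 + self.b1, self.slope)
        return spmm(A_norm, H1) @ self.W2 + self.b2


def encode(view, encoder: GCNEncoder) -> Tensor:
    """Encode an :class:`AugmentedView` or an ``(X, adjacency)`` pair,
    normalizing the (masked) adjacency internally."""
    if isinstance(view, AugmentedView):
        X, A = view.X_masked, view.adjacency_masked
    else:
        X, A = view
    return encoder.forward(np.asarray(X), normalize_adjacency(A))


def l2_normalize_rows(Z) -> Tensor:
    Z = as_tensor(Z)
    norms = ((Z * Z).sum(axis=1, keepdims=True) + _EPS * _EPS).sqrt()
    return Z / norms


def _infonce_pair_loss(Zn1: Tensor, Zn2: Tensor, tau: float, bonus: np.ndarray | None) -> Tensor:
    """Symmetrized (community-)InfoNCE on row-normalized embeddings.

    Implemented as one fused graph node: the similarity matrices, the
    stabilized softmax denominators and the closed-form gradient
    (softmax probabilities minus the positive-pair indicator) are computed
    with in-place numpy kernels, which keeps the O(n^2) temporaries to a
    minimum inside training loops.
    """
    A1, A2 = Zn1.data, Zn2.data
    n = A1.shape[0]
    inv_tau = np.asarray(1.0 / float(tau), dtype=A1.dtype)
    S12 = (A1 @ A2.T) * inv_tau
    S11 = (A1 @ A1.T) * inv_tau
    S22 = (A2 @ A2.T) * inv_tau
    if bonus is not None:
        bonus = np.asarray(bonus, dtype=A1.dtype)
        S12 += bonus
        S11 += bonus
        S22 += bonus
    diag12 = np.diag(S12).copy()

    def direction(Saa, Sab, pos_diag):
        # row-stabilized denominator over off-diagonal intra-view terms and
        # all cross-view terms; Saa is consumed (turned into probabilities)
        np.fill_diagonal(Saa, -np.inf)
        c = np.maximum(Saa.max(axis=1), Sab.max(axis=1))[:, None]
        Saa -= c
        np.exp(Saa, out=Saa)
        Eab = np.subtract(Sab, c)
        np.exp(Eab, out=Eab)
        D = Saa.sum(axis=1) + Eab.sum(axis=1)
        L_i = np.log(D) + c.ravel() - pos_diag
        Saa /= D[:, None]  # now the softmax probabilities P_aa
        Eab /= D[:, None]
        return float(L_i.mean()), Saa, Eab

    L2, P22, P21 = direction(S22, S12.T, diag12)  # before S12 is consumed
    L1, P11, P12 = direction(S11, S12, diag12)
    out = np.asarray(0.5 * (L1 + L2), dtype=A1.dtype)

    parents = []
    need1, need2 = Zn1.requires_grad, Zn2.requires_grad
    if need1 or need2:
        # G_ab = (P_ab - I)/n, G_aa = P_aa/n; the 1/n, 1/2 and 1/tau factors
        # are folded into the final scalar multiply
        idx = np.arange(n)
        P12[idx, idx] -= 1.0
        P21[idx, idx] -= 1.0
        scale = 0.5 / (float(tau) * n)

        if need1:
            def vjp1(g):
                grad = (P11 + P11.T) @ A1 + P12 @ A2 + P21.T @ A2
                grad *= float(g) * scale
                return grad

            parents.append((Zn1, vjp1))
        if need2:
            def vjp2(g):
                grad = (P22 + P22.T) @ A2 + P12.T @ A1 + P21 @ A1
                grad *= float(g) * scale
                return grad

            parents.append((Zn2, vjp2))
    return Tensor(out, parents=parents)


def infonce_loss(Z1, Z2, tau: float = 0.5) -> Tensor:
    """Symmetrized InfoNCE between two view embeddings.

    For each spot the positive is its counterpart in the other view; the
    denominator sums over the other spots of the same view and all spots of
    the other view. Returned as the mean of both directions.
    """
    return community_infonce_loss(Z1, Z2, partition=None, tau=tau, gamma=0.0)


def community_infonce_loss(
    Z1, Z2, partition: CommunityPartition | None, tau: float = 0.5, gamma: float = 0.0
) -> Tensor:
    """InfoNCE on community-bonused similarities.

    Every pairwise similarity (numerator and both denominator sums) receives
    the bonus gamma * (H_i + H_j) . S. With ``gamma=0`` (or one community)
    this reduces exactly to the plain InfoNCE loss.
    """
    Z1, Z2 = as_tensor(Z1), as_tensor(Z2)
    n = Z1.shape[0]
    if n == 0:
        raise ValueError("empty embeddings")
    if Z1.shape != Z2.shape:
        raise ValueError("view embeddings must share a shape")
    bonus = None
    if partition is not None and gamma != 0.0:
        if partition.assignment.shape[0] != n:
            raise ValueError("partition does not cover all spots")
        b = partition.H @ partition.strengths
        bonus = float(gamma) * (b[:, None] + b[None, :])
    Zn1, Zn2 = l2_normalize_rows(Z1), l2_normalize_rows(Z2)
    return _infonce_pair_loss(Zn1, Zn2, tau, bonus)


def gamma_schedule(k: int, k0: int, gamma_max: float) -> float:
    """Ramp from 0 after epoch k0 up to gamma_max: min(max(0, k - k0), gamma_max)."""
    if k < 0:
        raise ValueError("epoch must be nonnegative")
    return float(min(max(0, k - k0), gamma_max))


def _normalized_spatial_distances(coords: np.ndarray) -> np.ndarray:
    D = squareform(pdist(np.asarray(coords, dtype=float)))
    lo, hi = D.min(), D.max()
    if hi - lo < 1e-12:
        return np.zeros_like(D)
    return (D - lo) / (hi - lo)


def _minmax_tensor(D: Tensor) -> Tensor:
    """Differentiable min-max normalization of a distance tensor; an
    all-equal input maps to zeros."""
    if float(D.data.max()) - float(D.data.min()) < 1e-9:
        return D * 0.0
    lo = D.min()
    return (D - lo) / (D.max() - lo)


def _pairwise_embedding_distances(Z: Tensor) -> Tensor:
    """All-pairs Euclidean distances as one fused graph node.

    The vector-Jacobian product uses dD_ij/dZ_i = (Z_i - Z_j)/D_ij folded
    into two matrix products, avoiding per-element temporaries.
    """
    Z = as_tensor(Z)
    A = Z.data
    sq = (A * A).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (A @ A.T)
    np.maximum(D2, 0.0, out=D2)
    D = np.sqrt(D2 + np.asarray(1e-12, dtype=A.dtype), dtype=A.dtype)
    parents = []
    if Z.requires_grad:
        def vjp(g):
            M = (g + g.T) / D
            np.fill_diagonal(M, 0.0)
            return M.sum(axis=1)[:, None] * A - M @ A

        parents.append((Z, vjp))
    return Tensor(D, parents=parents)


def _spatial_regularizer_full(Z: Tensor, Ds: np.ndarray) -> Tensor:
    """Fused evaluation of sum_ij Ds_ij (1 - Dz_ij) / n^2 with Dz the
    min-max-normalized embedding distances.

    One graph node: the closed-form gradient chains through the weighted
    sum, the normalization scalars (subgradients at the arg-extrema) and the
    pairwise distances.
    """
    A = Z.data
    n = A.shape[0]
    sq = (A * A).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (A @ A.T)
    np.maximum(D, 0.0, out=D)
    np.sqrt(D + np.asarray(1e-12, dtype=A.dtype), out=D)
    i_lo = np.unravel_index(np.argmin(D), D.shape)
    i_hi = np.unravel_index(np.argmax(D), D.shape)
    lo, hi = float(D[i_lo]), float(D[i_hi])
    S1 = float(Ds.sum())
    SD = float(np.einsum("ij,ij->", Ds, D))
    inv_n2 = 1.0 / (n * n)
    if hi - lo < 1e-9:  # all-equal distances normalize to zero
        out = np.asarray(S1 * inv_n2, dtype=A.dtype)
        return Tensor(out, parents=[(Z, lambda g: np.zeros_like(A))] if Z.requires_grad else [])
    span = hi - lo
    out = np.asarray((S1 - (SD - lo * S1) / span) * inv_n2, dtype=A.dtype)
    parents = []
    if Z.requires_grad:
        def vjp(g):
            gD = Ds * np.asarray(-1.0 / (span * n * n), dtype=A.dtype)
            gD[i_lo] += (hi * S1 - SD) / (span * span * n * n)
            gD[i_hi] += (SD - lo * S1) / (span * span * n * n)
            M = (gD + gD.T) / D
            np.fill_diagonal(M, 0.0)
            grad = M.sum(axis=1)[:, None] * A - M @ A
            grad *= float(g)
            return grad

        parents.append((Z, vjp))
    return Tensor(out, parents=parents)


def within_slice_loss(
    Z,
    coords: np.ndarray,
    sample_pairs: int | None = None,
    rng: np.random.Generator | None = None,
    spatial_dist: np.ndarray | None = None,
) -> Tensor:
    """Spatial similarity regularizer for one slice.

    Full mode averages D^s_ij (1 - D^Z_ij) over all n^2 ordered pairs; with
    ``sample_pairs`` set, a seeded random subsample of ordered pairs (i != j)
    is averaged instead. ``spatial_dist`` may carry the precomputed
    normalized spatial distance matrix.
    """
    Z = as_tensor(Z)
    n = Z.shape[0]
    if n < 2:
        warnings.warn("within-slice loss needs >= 2 spots; returning 0", stacklevel=2)
        return Tensor(np.asarray(0.0, dtype=Z.dtype))
    if sample_pairs is None:
        Ds = (
            _normalized_spatial_distances(coords)
            if spatial_dist is None
            else np.asarray(spatial_dist)
        ).astype(Z.dtype)
        return _spatial_regularizer_full(Z, Ds)
    if rng is None:
        raise ValueError("sample_pairs requires a seeded rng")
    i = rng.integers(0, n, size=sample_pairs)
    off = rng.integers(1, n, size=sample_pairs)
    j = (i + off) % n  # j != i
    coords = np.asarray(coords, dtype=float)
    ds = np.linalg.norm(coords[i] - coords[j], axis=1)
    lo, hi = ds.min(), ds.max()
    ds = np.zeros_like(ds) if hi - lo < 1e-12 else (ds - lo) / (hi - lo)
    diff = take_rows(Z, i) - take_rows(Z, j)
    dz = _minmax_tensor(((diff * diff).sum(axis=1) + 1e-12).sqrt())
    return (Tensor(ds.astype(Z.dtype)) * (1.0 - dz)).mean()
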