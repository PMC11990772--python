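"""Encoder forward pass and contrastive / spatial loss values."""

import numpy as np
import pytest

from tacos.community import CommunityPartition
from tacos.encoder import (
    GCNEncoder,
    community_infonce_loss,
    encode,
    gamma_schedule,
    infonce_loss,
    within_slice_loss,
)
from tacos.spatial_graph import build_spatial_graph

from conftest import graph_from_edges


def brute_force_infonce(Z1, Z2, tau, bonus=None):
    """Naive double-loop oracle for the symmetrized (community-)InfoNCE loss."""

    def cos(u, v):
        return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

    def one_direction(A, B):
        n = len(A)
        total = 0.0
        for i in range(n):
            def s(u, v, j):
                base = cos(u, v) / tau
                return base + (bonus[i, j] if bonus is not None else 0.0)

            num = np.exp(s(A[i], B[i], i))
            den = sum(np.exp(s(A[i], A[j], j)) for j in range(n) if j != i)
            den += sum(np.exp(s(A[i], B[j], j)) for j in range(n))
            total += -np.log(num / den)
        return total / n

    return 0.5 * (one_direction(Z1, Z2) + one_direction(Z2, Z1))


# ---------------------------------------------------------------- encoder
def test_zero_weights_give_zero_embeddings():
    enc = GCNEncoder(n_genes=5, h=3, seed=0)
    for p in (enc.W1, enc.b1, enc.W2, enc.b2):
        p.data = np.zeros_like(p.data)
    graph = graph_from_edges([(0, 1)], 2)
    Z = encode((np.ones((2, 5)), graph.adjacency), enc)
    np.testing.assert_allclose(Z.data, 0.0)


def test_two_node_forward_matches_hand_computation():
    """One edge, identity features, hand-chosen small weights."""
    enc = GCNEncoder(n_genes=2, h=2, seed=0)
    W1 = np.array([[0.1, -0.2, 0.3, 0.0], [0.4, 0.5, -0.6, 0.2]])
    W2 = np.array([[0.2, 0.0], [-0.1, 0.3], [0.5, 0.1], [0.0, -0.4]])
    enc.W1.data = W1.astype(np.float32)
    enc.W2.data = W2.astype(np.float32)
    enc.b1.data[:] = 0.05
    enc.b2.data[:] = -0.02
    slope = 0.25
    graph = graph_from_edges([(0, 1)], 2)
    A_hat = 0.5 * np.ones((2, 2))  # normalized operator for a single edge
    X = np.eye(2)
    H_pre = A_hat @ X @ W1 + 0.05
    H = np.where(H_pre > 0, H_pre, slope * H_pre)
    expected = A_hat @ H @ W2 - 0.02
    Z = encode((X, graph.adjacency), enc)
    np.testing.assert_allclose(Z.data, expected, rtol=1e-5)


def test_isolated_node_embedding_depends_only_on_itself():
    enc = GCNEncoder(n_genes=4, h=2, seed=1)
    graph = graph_from_edges([(0, 1)], 3)  # node 2 isolated
    rng = np.random.default_rng(0)
    X = rng.uniform(size=(3, 4)).astype(np.float32)
    Z = encode((X, graph.adjacency), enc).data
    X2 = X.copy()
    X2[:2] = rng.uniform(size=(2, 4))  # perturb the others
    Z2 = encode((X2, graph.adjacency), enc).data
    np.testing.assert_allclose(Z[2], Z2[2], rtol=1e-5)


def test_encoder_permutation_equivariance():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 10, size=(30, 2))
    X = rng.uniform(size=(30, 6)).astype(np.float32)
    graph = build_spatial_graph(coords, k=3)
    enc = GCNEncoder(n_genes=6, h=4, seed=0)
    Z = encode((X, graph.adjacency), enc).data
    perm = rng.permutation(30)
    graph_p = build_spatial_graph(coords[perm], k=3)
    Zp = encode((X[perm], graph_p.adjacency), enc).data
    np.testing.assert_allclose(Zp, Z[perm], atol=1e-4)


# ---------------------------------------------------------------- InfoNCE
def test_infonce_single_spot_is_zero():
    Z = np.random.default_rng(0).normal(size=(1, 4))
    assert abs(float(infonce_loss(Z, Z + 0.3, tau=0.5))) < 1e-12


def test_infonce_identical_pair_is_log3():
    Z = np.tile(np.array([[1.0, 2.0, -1.0]]), (2, 1))
    assert abs(float(infonce_loss(Z, Z.copy(), tau=0.5)) - np.log(3.0)) < 1e-6


@pytest.mark.parametrize("seed", range(5))
def test_infonce_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 8))
    Z1 = rng.normal(size=(n, 5))
    Z2 = rng.normal(size=(n, 5))
    expected = brute_force_infonce(Z1, Z2, tau=0.7)
    assert abs(float(infonce_loss(Z1, Z2, tau=0.7)) - expected) < 1e-6


def test_infonce_nonnegative_and_empty_error():
    rng = np.random.default_rng(9)
    for _ in range(10):
        Z1, Z2 = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        assert float(infonce_loss(Z1, Z2, tau=0.5)) >= 0.0
    with pytest.raises(ValueError, match="empty"):
        infonce_loss(np.empty((0, 3)), np.empty((0, 3)))


def test_community_bonus_gamma_zero_reduces_to_plain(two_triangles_bridge):
    _, partition = two_triangles_bridge
    rng = np.random.default_rng(1)
    Z1, Z2 = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
    a = float(community_infonce_loss(Z1, Z2, partition, tau=0.5, gamma=0.0))
    b = float(infonce_loss(Z1, Z2, tau=0.5))
    assert abs(a - b) < 1e-9


def test_single_community_bonus_cancels(two_triangles_bridge):
    """A constant pairwise bonus is absorbed by the softmax."""
    graph, _ = two_triangles_bridge
    part = CommunityPartition.from_assignment(np.zeros(6, dtype=int), graph)
    part.strengths = np.array([0.37])
    rng = np.random.default_rng(2)
    Z1, Z2 = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
    with_bonus = float(community_infonce_loss(Z1, Z2, part, tau=0.5, gamma=2.0))
    plain = float(infonce_loss(Z1, Z2, tau=0.5))
    assert abs(with_bonus - plain) < 1e-5
    shifted = CommunityPartition.from_assignment(np.zeros(6, dtype=int), graph)
    shifted.strengths = part.strengths + 11.0
    again = float(community_infonce_loss(Z1, Z2, shifted, tau=0.5, gamma=2.0))
    assert abs(again - plain) < 1e-4


@pytest.mark.parametrize("seed", range(5))
def test_community_infonce_matches_brute_force(seed, two_triangles_bridge):
    _, partition = two_triangles_bridge
    rng = np.random.default_rng(seed)
    Z1, Z2 = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
    gamma = 0.8
    b = partition.H @ partition.strengths
    bonus = gamma * (b[:, None] + b[None, :])
    expected = brute_force_infonce(Z1, Z2, tau=0.7, bonus=bonus)
    got = float(community_infonce_loss(Z1, Z2, partition, tau=0.7, gamma=gamma))
    assert abs(got - expected) < 1e-6


# ------------------------------------------------------------- schedules
def test_gamma_schedule_values():
    assert gamma_schedule(100, 100, 1.0) == 0.0
    assert gamma_schedule(50, 100, 1.0) == 0.0
    assert gamma_schedule(150, 100, 1.0) == 1.0
    assert gamma_schedule(100, 100, 0.0) == 0.0
    assert gamma_schedule(100 + 1, 100, 5.0) == 1.0


# ------------------------------------------------------- spatial regularizer
def test_within_loss_identical_embeddings_two_spots():
    coords = np.array([[0.0, 0.0], [1.0, 0.0]])
    Z = np.ones((2, 3))
    assert abs(float(within_slice_loss(Z, coords)) - 0.5) < 1e-12


def test_within_loss_three_collinear_proportional():
    """Embedding distances proportional to spatial distances: terms D(1-D)."""
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    Z = np.array([[0.0, 0.0], [3.0, 0.0], [6.0, 0.0]])  # proportional
    # normalized distances: 0 (diag), 0.5 (adjacent), 1 (ends)
    expected = (4 * 0.5 * 0.5 + 2 * 1.0 * 0.0) / 9.0
    assert abs(float(within_slice_loss(Z, coords)) - expected) < 1e-6


def test_within_loss_degenerate_coordinates_zero():
    coords = np.zeros((4, 2))
    Z = np.random.default_rng(0).normal(size=(4, 3))
    assert float(within_slice_loss(Z, coords)) == 0.0
    with pytest.warns(UserWarning, match="2 spots"):
        assert float(within_slice_loss(Z[:1], coords[:1])) == 0.0


def test_within_loss_subsample_close_to_full():
    rng = np.random.default_rng(5)
    coords = rng.uniform(0, 10, size=(80, 2))
    Z = rng.normal(size=(80, 6))
    full = float(within_slice_loss(Z, coords))
    sub = float(
        within_slice_loss(Z, coords, sample_pairs=40_000, rng=np.random.default_rng(0))
    )
    assert abs(full - sub) < 0.02


def test_within_loss_prefers_spatially_faithful_embeddings():
    """Pulling near pairs together / pushing far pairs apart lowers the loss."""
    rng = np.random.default_rng(8)
    coords = rng.uniform(0, 10, size=(50, 2))
    faithful = np.hstack([coords, np.zeros((50, 1))])  # embeds spatial layout
    scrambled = faithful[rng.permutation(50)]
    assert float(within_slice_loss(faithful, coords)) < float(
        within_slice_loss(scrambled, coords)
    )
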