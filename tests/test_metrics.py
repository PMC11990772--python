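"""Integration metrics: extremes, hand cases and brute-force oracles."""

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import adjusted_rand_score

from tacos.metrics import (
    batch_entropy,
    cluster_embeddings,
    evaluate,
    graph_connectivity,
    lisi_scores,
    region_entropy,
    silhouette_scores,
)


def _mixed_fixture(n_per=60, seed=0):
    """Two batches drawn identically interleaved in one blob; two labels form
    two far-separated clusters."""
    rng = np.random.default_rng(seed)
    Z = np.vstack([rng.normal(0, 1, (n_per, 2)), rng.normal(20, 1, (n_per, 2))])
    labels = np.repeat(["a", "b"], n_per)
    batch = np.tile(["s1", "s2"], n_per)
    return Z, labels, batch


def _separated_fixture(n_per=60, seed=0):
    """Two batches in two far blobs (batch == blob)."""
    rng = np.random.default_rng(seed)
    Z = np.vstack([rng.normal(0, 1, (n_per, 2)), rng.normal(20, 1, (n_per, 2))])
    batch = np.repeat(["s1", "s2"], n_per)
    return Z, batch


def test_batch_entropy_extremes():
    Z, _, batch = _mixed_fixture()
    assert batch_entropy(Z, batch, k_region=20) > 0.95
    Zs, bs = _separated_fixture()
    assert batch_entropy(Zs, bs, k_region=20) < 0.05


def test_batch_entropy_weighted_hand_case():
    """Region with 3 spots of batch A (P=100) and 1 of B (P=50):
    corrected proportions (0.6, 0.4) -> 0.6730 nats."""
    ent = region_entropy(np.array([3, 1]), np.array([100, 50]))
    assert abs(ent - 0.6730116670092565) < 1e-10
    expected = -(0.6 * np.log(0.6) + 0.4 * np.log(0.4))
    assert abs(ent - expected) < 1e-12


def test_batch_entropy_size_correction():
    """Unequal batch sizes drawn from one distribution still score ~1: the
    regional proportions are corrected by total batch size."""
    rng = np.random.default_rng(3)
    Z = rng.normal(size=(150, 2))
    batch = np.array(["big"] * 100 + ["small"] * 50)
    assert batch_entropy(Z, batch, k_region=20) > 0.9


def test_batch_entropy_single_batch_error():
    Z, _, _ = _mixed_fixture(10)
    with pytest.raises(ValueError, match="two batches"):
        batch_entropy(Z, np.repeat("s1", len(Z)))


def test_silhouette_extremes():
    Z, labels, batch = _mixed_fixture()
    cASW, bASW = silhouette_scores(Z, labels, batch)
    assert cASW > 0.95  # far-separated, tight label clusters
    assert bASW > 0.95  # perfectly interleaved batches
    Zs, bs = _separated_fixture()
    labels_s = np.tile(["a", "b"], len(Zs) // 2)
    _, bASW_sep = silhouette_scores(Zs, labels_s, bs)
    assert bASW_sep < 0.1  # perfectly separated batches


def test_lisi_extremes():
    Z, labels, batch = _mixed_fixture()
    cLISI, bLISI = lisi_scores(Z, labels, batch, perplexity=15)
    assert bLISI > 0.9  # mixed batches -> x ~ 2
    assert cLISI > 0.9  # separated labels -> x ~ 1
    Zs, bs = _separated_fixture()
    labels_s = np.tile(["a", "b"], len(Zs) // 2)
    cLISI_s, bLISI_s = lisi_scores(Zs, labels_s, bs, perplexity=15)
    assert bLISI_s < 0.1  # separated batches
    with pytest.raises(ValueError, match="perplexity"):
        lisi_scores(Z[:10], np.tile(["a", "b"], 5), np.tile(["s1", "s2"], 5), perplexity=10)


def test_graph_connectivity_cases():
    rng = np.random.default_rng(1)
    Z = rng.normal(size=(30, 2))
    assert graph_connectivity(Z, np.repeat("a", 30), k_graph=5) == 1.0
    # label x splits into a 7-chain and a far 3-triangle (k=2 keeps them
    # apart) -> 0.7; label y is a connected square -> 1.0; mean 0.85
    chain = np.column_stack([np.arange(7.0), np.zeros(7)])
    triangle = np.array([[50.0, 0.0], [50.5, 0.5], [51.0, 0.0]])
    square = np.array([[0.0, 30.0], [1.0, 30.0], [1.0, 31.0], [0.0, 31.0]])
    Z2 = np.vstack([chain, triangle, square])
    labels2 = np.array(["x"] * 10 + ["y"] * 4)
    assert abs(graph_connectivity(Z2, labels2, k_graph=2) - 0.85) < 1e-12


@pytest.mark.parametrize("seed", range(10))
def test_graph_connectivity_matches_brute_force(seed):
    from sklearn.neighbors import kneighbors_graph

    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(40, 3))
    labels = rng.integers(0, 3, size=40)
    got = graph_connectivity(Z, labels, k_graph=4)
    scores = []
    for c in np.unique(labels):
        Zc = Z[labels == c]
        G = kneighbors_graph(Zc, n_neighbors=min(4, len(Zc) - 1))
        G = G.maximum(G.T)
        _, comp = connected_components(G, directed=False)
        scores.append(np.bincount(comp).max() / len(Zc))
    assert abs(got - np.mean(scores)) < 1e-12


def test_gmm_clustering_recovers_blobs_and_is_deterministic():
    rng = np.random.default_rng(4)
    Z = np.vstack([rng.normal(0, 0.5, (50, 2)), rng.normal(10, 0.5, (50, 2))])
    truth = np.repeat([0, 1], 50)
    labels = cluster_embeddings(Z, method="gmm", param=2, seed=0)
    assert adjusted_rand_score(truth, labels) == 1.0
    np.testing.assert_array_equal(
        labels, cluster_embeddings(Z, method="gmm", param=2, seed=0)
    )
    with pytest.raises(ValueError, match="n_components"):
        cluster_embeddings(Z[:3], method="gmm", param=5)


def test_leiden_low_resolution_single_cluster():
    rng = np.random.default_rng(5)
    Z = rng.normal(size=(60, 2))
    labels = cluster_embeddings(Z, method="leiden", param=1e-4, seed=0)
    assert len(np.unique(labels)) == 1
    l2 = cluster_embeddings(Z, method="leiden", param=1.0, seed=3)
    np.testing.assert_array_equal(l2, cluster_embeddings(Z, method="leiden", param=1.0, seed=3))


def test_louvain_runs_and_is_seeded():
    rng = np.random.default_rng(6)
    Z = np.vstack([rng.normal(0, 0.5, (40, 2)), rng.normal(8, 0.5, (40, 2))])
    a = cluster_embeddings(Z, method="louvain", param=1.0, seed=1)
    b = cluster_embeddings(Z, method="louvain", param=1.0, seed=1)
    np.testing.assert_array_equal(a, b)
    # clusters never mix the two blobs (each cluster is pure)
    blob = np.repeat([0, 1], 40)
    for c in np.unique(a):
        assert len(np.unique(blob[a == c])) == 1


def test_evaluate_report_in_unit_interval():
    Z, labels, batch = _mixed_fixture()
    report = evaluate(Z, labels, batch, k_region=15, perplexity=10, k_graph=5)
    for key, val in report.to_dict().items():
        if key == "params":
            continue
        assert 0.0 <= val <= 1.0, key
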