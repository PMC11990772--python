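"""Integration-quality metrics and spatial-domain clustering.

Batch-mixing scores (batch entropy, bASW, bLISI, graph connectivity) reward
embeddings in which slices are well interleaved; biology-conservation
scores (cASW, cLISI) reward separation of annotated labels. All scores are
reported on a 0-1 scale with 1 best.

* Batch entropy: for each spot the batch composition of its k-nearest
  neighborhood is corrected by total batch sizes, renormalized, and scored
  by Shannon entropy; the mean over spots is divided by log(#batches).
* ASW: silhouette per spot; cASW = mean((s+1)/2) on labels, bASW =
  mean(1 - |s|) on batches so perfect mixing scores 1.
* LISI: perplexity-calibrated inverse Simpson index of neighborhood
  category probabilities; rescaled so bLISI = median(x-1)/(B-1) and
  cLISI = median(C-x)/(C-1).
* Graph connectivity: per label, the largest-connected-component fraction
  of the label's kNN subgraph, averaged over labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import silhouette_samples
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors, kneighbors_graph


@dataclass
class MetricReport:
    """All integration scores plus the parameters used to compute them."""

    batch_entropy: float
    cASW: float
    bASW: float
    cLISI: float
    bLISI: float
    graph_connectivity: float
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "batch_entropy": self.batch_entropy,
            "cASW": self.cASW,
            "bASW": self.bASW,
            "cLISI": self.cLISI,
            "bLISI": self.bLISI,
            "graph_connectivity": self.graph_connectivity,
            "params": self.params,
        }


def _as_codes(values) -> tuple[np.ndarray, int]:
    values = np.asarray(values)
    _, codes = np.unique(values, return_inverse=True)
    return codes, int(codes.max()) + 1


def batch_entropy(Z: np.ndarray, batch, k_region: int = 30) -> float:
    """Size-corrected neighborhood batch entropy, normalized to [0, 1].

    Each spot's region is its ``k_region`` nearest neighbors (self
    excluded). Regional batch proportions are divided by the total size of
    each batch, renormalized, and scored with Shannon entropy; the mean over
    spots is divided by log(#batches).
    """
    Z = np.asarray(Z)
    codes, B = _as_codes(batch)
    if B < 2:
        raise ValueError("batch entropy needs at least two batches")
    n = Z.shape[0]
    k = min(k_region, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    _, idx = nn.kneighbors(Z)
    idx = idx[:, 1:]
    sizes = np.bincount(codes, minlength=B).astype(float)
    neigh_codes = codes[idx]  # (n, k)
    counts = np.stack([(neigh_codes == b).sum(axis=1) for b in range(B)], axis=1)
    corrected = counts / k / sizes[None, :]
    corrected /= corrected.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(corrected > 0, corrected * np.log(corrected), 0.0)
    ent = -terms.sum(axis=1)
    return float(ent.mean() / np.log(B))


def region_entropy(counts: np.ndarray, batch_sizes: np.ndarray) -> float:
    """Entropy (nats) of one region's size-corrected batch proportions.

    Exposed separately so hand-computable cases can be checked directly.
    """
    counts = np.asarray(counts, dtype=float)
    corrected = counts / counts.sum() / np.asarray(batch_sizes, dtype=float)
    corrected /= corrected.sum()
    nz = corrected[corrected > 0]
    return float(-(nz * np.log(nz)).sum())


def silhouette_scores(Z: np.ndarray, labels, batches, use_pca: bool = False) -> tuple:
    """(cASW, bASW) silhouette-based scores.

    cASW rescales label silhouettes to [0, 1]; bASW uses 1 - |s| on batch
    silhouettes so that perfectly mixed batches score 1. ``use_pca``
    projects to the top 20 principal components first (useful for
    high-dimensional inputs).
    """
    Z = np.asarray(Z)
    if use_pca and Z.shape[1] > 20:
        from sklearn.decomposition import PCA

        Z = PCA(n_components=20, random_state=0).fit_transform(Z)
    lab_codes, n_lab = _as_codes(labels)
    bat_codes, n_bat = _as_codes(batches)
    if n_lab < 2:
        raise ValueError("cASW needs at least two label categories")
    if n_bat < 2:
        raise ValueError("bASW needs at least two batches")
    singles = [c for c in range(n_lab) if (lab_codes == c).sum() == 1]
    if singles:
        warnings.warn(
            f"{len(singles)} label categor(ies) with a single member score 0",
            stacklevel=2,
        )
    s_lab = silhouette_samples(Z, lab_codes)
    s_bat = silhouette_samples(Z, bat_codes)
    cASW = float(((s_lab + 1.0) / 2.0).mean())
    bASW = float((1.0 - np.abs(s_bat)).mean())
    return cASW, bASW


def _lisi_per_spot(Z: np.ndarray, codes: np.ndarray, n_cat: int, perplexity: float) -> np.ndarray:
    """Perplexity-calibrated inverse Simpson index per spot."""
    n = Z.shape[0]
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < number of spots ({n})")
    k = min(n - 1, max(int(3 * perplexity), 2))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    dist, idx = nn.kneighbors(Z)
    dist, idx = dist[:, 1:], idx[:, 1:]
    d2 = dist**2
    target = np.log(perplexity)
    x = np.empty(n)
    for i in range(n):
        lo, hi = 0.0, np.inf
        beta = 1.0
        for _ in range(60):
            w = np.exp(-beta * d2[i])
            sw = w.sum()
            if sw <= 0:
                p = np.full(k, 1.0 / k)
                break
            p = w / sw
            ent = -(p[p > 0] * np.log(p[p > 0])).sum()
            if abs(ent - target) < 1e-5:
                break
            if ent > target:  # too flat -> sharpen
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else (beta + hi) / 2.0
            else:
                hi = beta
                beta = beta / 2.0 if lo == 0.0 else (beta + lo) / 2.0
        probs = np.zeros(n_cat)
        np.add.at(probs, codes[idx[i]], p)
        x[i] = 1.0 / (probs**2).sum()
    return x


def lisi_scores(Z: np.ndarray, labels, batches, perplexity: float = 30.0) -> tuple:
    """(cLISI, bLISI) rescaled to [0, 1].

    bLISI = median(x_b - 1)/(B - 1) rewards batch mixing; cLISI =
    median(C - x_c)/(C - 1) rewards label separation, with B batches and C
    label categories.
    """
    Z = np.asarray(Z)
    lab_codes, C = _as_codes(labels)
    bat_codes, B = _as_codes(batches)
    if C < 2 or B < 2:
        raise ValueError("LISI scores need >= 2 categories for labels and batches")
    x_lab = _lisi_per_spot(Z, lab_codes, C, perplexity)
    x_bat = _lisi_per_spot(Z, bat_codes, B, perplexity)
    cLISI = float(np.median(C - x_lab) / (C - 1))
    bLISI = float(np.median(x_bat - 1) / (B - 1))
    return cLISI, bLISI


def graph_connectivity(Z: np.ndarray, labels, k_graph: int = 15) -> float:
    """Mean over labels of the largest-connected-component fraction of each
    label's kNN subgraph."""
    Z = np.asarray(Z)
    codes, C = _as_codes(labels)
    n = Z.shape[0]
    scores = []
    for c in range(C):
        mask = codes == c
        Zc = Z[mask]
        nc = Zc.shape[0]
        if nc == 1:
            scores.append(1.0)
            continue
        k = min(k_graph, nc - 1)
        G = kneighbors_graph(Zc, n_neighbors=k, mode="connectivity")
        G = G.maximum(G.T)
        n_comp, comp = connected_components(G, directed=False)
        largest = np.bincount(comp).max()
        scores.append(largest / nc)
    return float(np.mean(scores))


def cluster_embeddings(
    Z: np.ndarray,
    method: str = "leiden",
    param: float | int = 1.0,
    seed: int = 0,
    k_graph: int = 15,
) -> np.ndarray:
    """Cluster spots in embedding space.

    ``leiden``/``louvain`` run on a symmetrized kNN graph at resolution
    ``param``; ``gmm`` fits a Gaussian mixture with ``param`` components
    (EM, the mclust-style option recommended for Visium-like data) and
    returns hard assignments. Deterministic for a fixed seed.
    """
    Z = np.asarray(Z)
    n = Z.shape[0]
    if method == "gmm":
        n_comp = int(param)
        if n_comp > n:
            raise ValueError(f"n_components ({n_comp}) exceeds number of spots ({n})")
        gm = GaussianMixture(n_components=n_comp, random_state=seed, n_init=3)
        return gm.fit_predict(Z)
    if method not in ("leiden", "louvain"):
        raise ValueError(f"unknown clustering method {method!r}")
    import igraph
    import leidenalg

    k = min(k_graph, n - 1)
    G = kneighbors_graph(Z, n_neighbors=k, mode="connectivity")
    G = G.maximum(G.T).tocoo()
    upper = G.row < G.col
    edges = list(zip(G.row[upper].tolist(), G.col[upper].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    if method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(param),
            seed=int(seed),
        )
        return np.asarray(part.membership, dtype=int)
    import random

    random.seed(int(seed))
    part = g.community_multilevel(resolution=float(param))
    return np.asarray(part.membership, dtype=int)


def leiden_at_k(
    Z: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    resolutions=(0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 1.5, 2.0),
    k_graph: int = 15,
) -> np.ndarray:
    """Leiden clustering targeting a known number of spatial domains.

    Sweeps the resolution parameter and returns the partition whose cluster
    count is closest to ``n_clusters`` (ties broken toward lower
    resolution). Mirrors the common workflow of matching an anatomically
    known domain count.
    """
    best, best_diff = None, None
    for res in resolutions:
        labels = cluster_embeddings(Z, method="leiden", param=res, seed=seed, k_graph=k_graph)
        diff = abs(len(np.unique(labels)) - n_clusters)
        if best is None or diff < best_diff:
            best, best_diff = labels, diff
        if diff == 0:
            break
    return best


def evaluate(
    Z: np.ndarray,
    labels,
    batches,
    k_region: int = 30,
    perplexity: float = 30.0,
    k_graph: int = 15,
    use_pca: bool = False,
) -> MetricReport:
    """Compute the full integration-quality report."""
    cASW, bASW = silhouette_scores(Z, labels, batches, use_pca=use_pca)
    cLISI, bLISI = lisi_scores(Z, labels, batches, perplexity=perplexity)
    return MetricReport(
        batch_entropy=batch_entropy(Z, batches, k_region=k_region),
        cASW=cASW,
        bASW=bASW,
        cLISI=cLISI,
        bLISI=bLISI,
        graph_connectivity=graph_connectivity(Z, labels, k_graph=k_graph),
        params={
            "k_region": k_region,
            "perplexity": perplexity,
            "k_graph": k_graph,
            "use_pca": use_pca,
        },
    )
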