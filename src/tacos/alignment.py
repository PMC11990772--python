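"""Cross-slice alignment and the end-to-end two-stage integration procedure.

Slices are embedded by one shared graph-convolutional encoder so that all
spots live in a common h-dimensional space. Training proceeds in two
stages:

1. *Pretraining* — per-slice contrastive learning between two uniformly
   perturbed graph views, plus the spatial regularizer.
2. *Community-enhanced training* — communities are detected on the
   pretrained embeddings, augmented views are drawn with the community-aware
   masking policies, and the contrastive loss receives the community
   similarity bonus with a ramped coefficient. In this stage mutual nearest
   neighbor (MNN) pairs between slices are re-detected every refresh
   interval on the current embeddings, and a triplet hinge loss pulls each
   anchor toward its cross-slice positive relative to a random same-slice
   negative, removing batch effects while preserving structure.

The total objective is

    L = sum_t L_t + alpha * sum_t L_within^t + beta * sum_{t1<t2} L_across^{t1,t2}

optimized with Adam (learning rate 1e-3, 2000 epochs by default). Slices
are processed one at a time each epoch, accumulating gradients before a
single optimizer step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._autodiff import Adam, Tensor, take_rows
from .augmentation import (
    attribute_mask_weights,
    edge_mask_weights,
    random_view,
    sample_view,
)
from .community import detect_communities
from .encoder import (
    GCNEncoder,
    community_infonce_loss,
    encode,
    gamma_schedule,
    infonce_loss,
    l2_normalize_rows,
    within_slice_loss,
    _normalized_spatial_distances,
)
from .errors import DivergenceError
from .slice_io import LOG_NORMALIZED
from .spatial_graph import build_spatial_graph, normalize_adjacency

logger = logging.getLogger(__name__)


@dataclass
class TripletSet:
    """Anchor / positive / negative index triplets for one ordered slice pair."""

    anchors: np.ndarray  # indices in the anchor slice
    positives: np.ndarray  # indices in the other slice
    negatives: np.ndarray  # indices in the anchor slice

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=int)
        self.positives = np.asarray(self.positives, dtype=int)
        self.negatives = np.asarray(self.negatives, dtype=int)
        if not (len(self.anchors) == len(self.positives) == len(self.negatives)):
            raise ValueError("triplet arrays must have equal length")

    @property
    def n_triplets(self) -> int:
        return len(self.anchors)


@dataclass
class EmbeddingSet:
    """Per-slice embeddings in a shared space plus training bookkeeping."""

    slice_ids: list
    embeddings: dict  # slice_id -> (n_t, h) ndarray
    history: pd.DataFrame
    mnn_pairs: dict = field(default_factory=dict)  # (id1, id2) -> (P, 2) ndarray

    def concatenated(self):
        Z = np.vstack([self.embeddings[s] for s in self.slice_ids])
        batch = np.concatenate(
            [np.repeat(s, len(self.embeddings[s])) for s in self.slice_ids]
        )
        return Z, batch


def find_mnn_pairs(Z_a: np.ndarray, Z_b: np.ndarray, k_mnn: int = 5) -> np.ndarray:
    """Mutual nearest neighbor pairs between two embedding matrices.

    Pair (i, j) is kept iff j is among the k nearest rows of ``Z_b`` to
    ``Z_a[i]`` (Euclidean) and i is among the k nearest rows of ``Z_a`` to
    ``Z_b[j]``. Returns an (P, 2) integer array.
    """
    Z_a, Z_b = np.asarray(Z_a), np.asarray(Z_b)
    if Z_a.shape[0] == 0 or Z_b.shape[0] == 0:
        raise ValueError("cannot find MNN pairs with an empty slice")
    if Z_a.shape[1] != Z_b.shape[1]:
        raise ValueError("embeddings must share their dimension")
    ka = min(k_mnn, Z_b.shape[0])
    kb = min(k_mnn, Z_a.shape[0])
    nn_b = NearestNeighbors(n_neighbors=ka).fit(Z_b)
    _, ab = nn_b.kneighbors(Z_a)  # for each a: its k nearest b's
    nn_a = NearestNeighbors(n_neighbors=kb).fit(Z_a)
    _, ba = nn_a.kneighbors(Z_b)
    b_neighbors = [set(row) for row in ba]
    pairs = [
        (i, int(j))
        for i in range(Z_a.shape[0])
        for j in ab[i]
        if i in b_neighbors[int(j)]
    ]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def sample_triplets(pairs: np.ndarray, n_a: int, rng: np.random.Generator) -> TripletSet:
    """One triplet per MNN pair; the negative is drawn uniformly from the
    anchor's slice excluding the anchor itself."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if pairs.shape[0] == 0:
        raise ValueError("no MNN pairs to sample triplets from")
    if n_a < 2:
        warnings.warn("anchor slice has a single spot; no negatives available", stacklevel=2)
        return TripletSet(np.empty(0, int), np.empty(0, int), np.empty(0, int))
    anchors = pairs[:, 0]
    positives = pairs[:, 1]
    offs = rng.integers(1, n_a, size=pairs.shape[0])
    negatives = (anchors + offs) % n_a  # uniform over indices != anchor
    return TripletSet(anchors, positives, negatives)


def triplet_loss(Z_anchor_slice, Z_positive_slice, triplets: TripletSet, theta: float = 1.0):
    """Mean hinge loss max(||Z_a - Z_p||^2 - ||Z_a - Z_n||^2 + theta, 0)."""
    if triplets.n_triplets == 0:
        warnings.warn("empty triplet set; across-slice loss is 0", stacklevel=2)
        return Tensor(np.asarray(0.0))
    Za = Z_anchor_slice if isinstance(Z_anchor_slice, Tensor) else Tensor(np.asarray(Z_anchor_slice))
    Zp = (
        Z_positive_slice
        if isinstance(Z_positive_slice, Tensor)
        else Tensor(np.asarray(Z_positive_slice))
    )
    A = take_rows(Za, triplets.anchors)
    P = take_rows(Zp, triplets.positives)
    N = take_rows(Za, triplets.negatives)
    d_ap = ((A - P) * (A - P)).sum(axis=1)
    d_an = ((A - N) * (A - N)).sum(axis=1)
    return (d_ap - d_an + float(theta)).relu().mean()


@dataclass
class IntegrationConfig:
    """Configuration of the full integration procedure (all defaults exposed
    in the YAML config consumed by the CLI)."""

    h: int = 50
    lr: float = 1e-3
    epochs: int = 2000
    stage1_epochs: int = 200
    mnn_refresh: int = 25
    k_mnn: int = 5
    tau: float = 0.5
    alpha: float = 0.1
    beta: float = 1.0
    theta: float = 1.0
    gamma_k0: int | None = None  # default: 0.1 * epochs
    gamma_max: float = 1.0
    p_attr_1: float = 0.3
    p_attr_2: float = 0.4
    p_edge_1: float = 0.9
    p_edge_2: float = 0.9
    edge_keep_floor: float = 0.0
    stage1_p_edge_drop: float = 0.2
    graph_k: int = 6
    leiden_resolution: float = 1.0
    pair_subsample_threshold: int = 3000
    pair_subsample: int = 50_000
    bidirectional_triplets: bool = True
    resample_negatives: bool = False  # fresh random negatives every epoch
    seed: int = 0
    dtype: str = "float32"

    def resolved_gamma_k0(self) -> int:
        return int(0.1 * self.epochs) if self.gamma_k0 is None else int(self.gamma_k0)


def integrate(slices: list, config: IntegrationConfig | None = None, **overrides) -> EmbeddingSet:
    """Run the full two-stage integration over >= 2 preprocessed slices.

    All slices must be log-normalized and share an identical gene column
    order (see :func:`tacos.slice_io.select_shared_hvgs`). Returns the final
    per-slice embeddings, the per-epoch loss history and the final MNN
    pairs.
    """
    cfg = config or IntegrationConfig()
    if overrides:
        cfg = IntegrationConfig(**{**cfg.__dict__, **overrides})
    if len(slices) < 2:
        raise ValueError("integration needs at least two slices")
    genes = slices[0].gene_ids
    for s in slices[1:]:
        if s.gene_ids != genes:
            raise ValueError(
                f"slice {s.slice_id!r} gene columns differ from {slices[0].slice_id!r}; "
                "run select_shared_hvgs first"
            )
    for s in slices:
        if s.processing != LOG_NORMALIZED:
            warnings.warn(
                f"slice {s.slice_id!r} is not log_normalized; integrating as-is",
                stacklevel=2,
            )

    dtype = np.dtype(cfg.dtype)
    rng = np.random.default_rng(cfg.seed)
    aug_rng = np.random.default_rng(rng.integers(2**31))
    trip_rng = np.random.default_rng(rng.integers(2**31))
    pair_rng = np.random.default_rng(rng.integers(2**31))
    leiden_seed = int(rng.integers(2**31))
    init_seed = int(rng.integers(2**31))

    T = len(slices)
    ids = [s.slice_id for s in slices]
    if len(set(ids)) != T:
        ids = [f"{s.slice_id}#{t}" for t, s in enumerate(slices)]
    X = [np.ascontiguousarray(s.X, dtype=dtype) for s in slices]
    graphs = [build_spatial_graph(s.coords, k=cfg.graph_k) for s in slices]
    A_norm = [normalize_adjacency(g).astype(dtype) for g in graphs]
    use_full_pairs = [s.n_spots <= cfg.pair_subsample_threshold for s in slices]
    Ds_norm = [
        _normalized_spatial_distances(s.coords).astype(dtype) if full else None
        for s, full in zip(slices, use_full_pairs)
    ]

    encoder = GCNEncoder(len(genes), h=cfg.h, seed=init_seed, dtype=dtype)
    optimizer = Adam(encoder.parameters(), lr=cfg.lr)
    k0 = cfg.resolved_gamma_k0()

    partitions = [None] * T
    attr_w = [None] * T
    edge_w = [None] * T
    triplets: dict[tuple[int, int], TripletSet] = {}
    mnn_current: dict[tuple[int, int], np.ndarray] = {}
    slice_pairs = [(a, b) for a in range(T) for b in range(T) if a < b]
    history: list[dict] = []

    def _check(value: float, epoch: int, component: str) -> float:
        if not np.isfinite(value):
            raise DivergenceError(epoch, component)
        return value

    def _within(Zf, t):
        if use_full_pairs[t]:
            return within_slice_loss(Zf, slices[t].coords, spatial_dist=Ds_norm[t])
        return within_slice_loss(
            Zf, slices[t].coords, sample_pairs=cfg.pair_subsample, rng=pair_rng
        )

    for epoch in range(cfg.epochs):
        stage2 = epoch >= cfg.stage1_epochs
        if epoch == cfg.stage1_epochs:
            # stage boundary: refresh communities from the pretrained embeddings
            for t in range(T):
                Zf = encoder.forward(X[t], A_norm[t]).data
                partitions[t] = detect_communities(
                    slices[t],
                    graphs[t],
                    mode="embedding",
                    embedding=Zf,
                    resolution=cfg.leiden_resolution,
                    seed=leiden_seed,
                )
                attr_w[t] = attribute_mask_weights(X[t], partitions[t])
                edge_w[t] = edge_mask_weights(graphs[t], partitions[t])
                logger.info(
                    "slice %s: %d communities at stage boundary",
                    ids[t],
                    partitions[t].n_communities,
                )
        row = {"epoch": epoch, "stage": 2 if stage2 else 1}
        gamma = gamma_schedule(epoch, k0, cfg.gamma_max) if stage2 else 0.0
        row["gamma"] = gamma

        z_full: list[Tensor] = []
        for t in range(T):
            if stage2:
                v1 = sample_view(
                    X[t], graphs[t], partitions[t], cfg.p_attr_1, cfg.p_edge_1,
                    aug_rng, cfg.edge_keep_floor, attr_w[t], edge_w[t],
                )
                v2 = sample_view(
                    X[t], graphs[t], partitions[t], cfg.p_attr_2, cfg.p_edge_2,
                    aug_rng, cfg.edge_keep_floor, attr_w[t], edge_w[t],
                )
            else:
                v1 = random_view(X[t], graphs[t], cfg.p_attr_1, cfg.stage1_p_edge_drop, aug_rng)
                v2 = random_view(X[t], graphs[t], cfg.p_attr_2, cfg.stage1_p_edge_drop, aug_rng)
            Z1 = encode(v1, encoder)
            Z2 = encode(v2, encoder)
            if stage2:
                L_c = community_infonce_loss(Z1, Z2, partitions[t], tau=cfg.tau, gamma=gamma)
            else:
                L_c = infonce_loss(Z1, Z2, tau=cfg.tau)
            Zf = encoder.forward(X[t], A_norm[t])
            L_w = _within(Zf, t)
            loss_t = L_c + cfg.alpha * L_w
            row[f"contrastive_{ids[t]}"] = _check(L_c.item(), epoch, f"contrastive[{ids[t]}]")
            row[f"within_{ids[t]}"] = _check(L_w.item(), epoch, f"within[{ids[t]}]")
            loss_t.backward()
            z_full.append(Zf)

        if stage2 and slice_pairs:
            # alignment operates on the unit sphere: the contrastive loss is
            # cosine-based, and normalizing makes the triplet margin
            # scale-free (raw embedding norms grow during training, which
            # would let random negatives satisfy the margin trivially)
            z_unit = [l2_normalize_rows(z) for z in z_full]
            if (epoch - cfg.stage1_epochs) % cfg.mnn_refresh == 0:
                # anchoring from both slices of each pair: the MNN relation
                # is symmetric, and one-sided anchoring halves the signal
                directed = list(slice_pairs)
                if cfg.bidirectional_triplets:
                    directed += [(b, a) for a, b in slice_pairs]
                for t1, t2 in directed:
                    pairs = find_mnn_pairs(z_unit[t1].data, z_unit[t2].data, cfg.k_mnn)
                    if pairs.shape[0] == 0:
                        warnings.warn(
                            f"no MNN pairs between {ids[t1]} and {ids[t2]} at epoch {epoch}",
                            stacklevel=2,
                        )
                    mnn_current[(t1, t2)] = pairs
                    triplets[(t1, t2)] = (
                        sample_triplets(pairs, slices[t1].n_spots, trip_rng)
                        if pairs.shape[0]
                        else TripletSet(np.empty(0, int), np.empty(0, int), np.empty(0, int))
                    )
            L_across_total = None
            for t1, t2 in list(triplets):
                if cfg.resample_negatives and mnn_current[(t1, t2)].shape[0]:
                    triplets[(t1, t2)] = sample_triplets(
                        mnn_current[(t1, t2)], slices[t1].n_spots, trip_rng
                    )
                trip = triplets[(t1, t2)]
                key = f"across_{ids[t1]}_{ids[t2]}"
                if trip.n_triplets == 0:
                    row[key] = 0.0
                    continue
                L_a = triplet_loss(z_unit[t1], z_unit[t2], trip, theta=cfg.theta)
                row[key] = _check(L_a.item(), epoch, f"across[{ids[t1]},{ids[t2]}]")
                L_across_total = L_a if L_across_total is None else L_across_total + L_a
            if L_across_total is not None and cfg.beta != 0.0:
                (cfg.beta * L_across_total).backward()

        optimizer.step()
        optimizer.zero_grad()
        history.append(row)

    embeddings = {
        ids[t]: encoder.forward(X[t], A_norm[t]).data.astype(np.float64) for t in range(T)
    }
    unit = {k: v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-8)
            for k, v in embeddings.items()}
    mnn_final = {
        (ids[t1], ids[t2]): find_mnn_pairs(unit[ids[t1]], unit[ids[t2]], cfg.k_mnn)
        for t1, t2 in slice_pairs
    }
    # components that do not apply to an epoch (e.g. across-slice terms
    # before stage 2) are recorded as 0
    return EmbeddingSet(ids, embeddings, pd.DataFrame(history).fillna(0.0), mnn_final)
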