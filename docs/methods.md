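# Methods

## Model overview

`tacos` embeds two or more spatial transcriptomics slices into one
h-dimensional space (default h = 50) with a single shared two-layer graph
convolutional encoder

    Z_t = Â_t · PReLU(Â_t X_t W1 + b1) · W2 + b2,

where X_t is the log-normalized expression of slice t restricted to the
genes shared by all slices, and Â_t = D̃^{-1/2}(A_t + I)D̃^{-1/2} is the
symmetrically normalized spatial adjacency. Because the encoder weights are
shared and the gene columns are identical across slices, all slices land in
one coordinate system; batch-effect removal is then driven by the
cross-slice alignment term rather than by per-slice reparameterization.

### Assumptions

- Spots of one slice lie in a 2-D plane and spatial proximity implies an
  elevated chance of shared expression program.
- Slices profile the same kind of tissue, so for most spots a biological
  counterpart exists in the other slices (MNN pairs are meaningful).
- Batch effects are expressed as per-gene systematic shifts; they do not
  reorder the relative structure of domains within a slice.

## Pipeline stages

1. **Preprocessing** (`slice_io`). Counts are scaled per spot to a total of
   10,000 and transformed by ln(1+x). Zero-count spots are kept as all-zero
   rows (dropping them would desynchronize the coordinate table) with a
   warning. Per-slice highly variable genes are ranked by a
   variance-stabilized score: a lowess trend of log10 variance against
   log10 mean is fitted on raw counts, each gene is standardized by its
   trend-expected standard deviation with clipping at sqrt(n), and the
   variance of the standardized values is ranked. Slices with fewer than
   `n_top` (default 3000) genes contribute their whole gene list. The
   slices are subset to the intersection of the per-slice sets, columns
   sorted lexicographically so results do not depend on input column order.

2. **Spatial graph** (`spatial_graph`). The neighborhood radius r is the
   global mean over spots of each spot's mean Euclidean distance to its k
   nearest neighbors (default k = 6, matching hexagonal Visium
   neighborhoods). The graph keeps Delaunay edges of length at most 2r
   (closed threshold). For Gabriel edges this is exactly the alpha-complex
   condition — the nearest point of the shared Voronoi facet is the
   midpoint at distance L/2 — while non-Gabriel Delaunay edges are slightly
   over-included; the construction is robust and adapts to non-uniform
   densities. Collinear or sub-3-point inputs fall back to a symmetrized
   kNN graph with the same k.

3. **Communities** (`community`). Leiden modularity optimization runs on
   the spatial graph with edge weights equal to the cosine similarity
   (clipped at 0) of the endpoints' features — log-normalized expression in
   stage 1, the current embedding at the stage boundary. Community
   strengths S_c = E_c/|E| − (Σ d_v)²/(4|E|²) sum to the partition's Newman
   modularity (this identity is the module's primary correctness oracle);
   they may be negative for weak communities and are not clipped.

4. **Augmentation** (`augmentation`). Gene masking weights are
   w = Norm(|XᵀH S|) and edge weights are the shared community strength for
   intra-community edges and −(H_i·S + H_j·S) otherwise, where Norm is
   min-max to [0, 1] with all-equal vectors mapped to 0.5. A view keeps
   gene g with probability 1 − w_g p_attr (column-wise, broadcast over
   spots) and keeps edge e with probability w_e p_edge (interpreting the
   edge Bernoulli literally as a keep probability; defaults
   p_edge = 0.9 so strong intra-community edges survive while
   inter-community edges are usually dropped; an optional floor can lift
   the minimum keep probability). Stage-1 pretraining uses uniform gene
   masking (p_attr_1 = 0.3, p_attr_2 = 0.4 — two views must differ) and
   uniform edge dropping (probability 0.2).

5. **Losses** (`encoder`, `alignment`).
   - InfoNCE with temperature τ (default 0.5) between the two views,
     symmetrized as the mean of both directions; the denominator contains
     the other spots of the same view and all spots of the other view.
   - The community-enhanced variant adds γ_k (H_i + H_j)·S to every
     pairwise similarity (numerator and both denominator sums), with
     γ_k = min(max(0, k − k0), γ_max), k0 = 0.1 · total epochs,
     γ_max = 1 by default. With one community the bonus is constant and
     cancels in the softmax.
   - Spatial regularizer Σ_ij D^s_ij (1 − D^Z_ij)/n², both distance
     matrices min-max normalized over the evaluated pairs; slices above
     3,000 spots use a seeded 50,000-pair subsample instead of the full
     double sum. All-equal distance matrices normalize to zero.
   - Cross-slice term: MNN pairs (mutual membership in each other's k = 5
     nearest neighbor lists, Euclidean, in embedding space) give anchors
     and positives; negatives are drawn uniformly from the anchor's slice
     excluding the anchor; the hinge
     max(‖Z_a − Z_p‖² − ‖Z_a − Z_n‖² + θ, 0) with margin θ = 1 is averaged
     over triplets, anchoring from both slices of each pair (the MNN
     relation is symmetric). Inside the training loop, MNN detection and
     the hinge operate on L2-normalized embeddings: the contrastive loss is
     cosine-based, so raw norms grow freely during training and would make
     the fixed margin negligible against squared distances; on the unit
     sphere squared distances lie in [0, 4] and the margin stays
     meaningful. Pairs and triplets are refreshed every 25 epochs — the
     embedding drifts during training, and with stale pairs the hinge
     saturates and alignment stalls. An option draws fresh random negatives
     every epoch (off by default; it showed no measurable benefit).
   - Total objective L = Σ_t L_t + α Σ_t L_within + β Σ_{t1<t2} L_across
     with α = 0.1, β = 1.

6. **Training schedule** (`alignment.integrate`). Adam, learning rate
   1e-3, 2000 epochs by default, stage 1 (uniform augmentations, plain
   InfoNCE) for the first 200 epochs; communities are detected once at the
   stage boundary from the pretrained embeddings; stage 2 uses the
   community-aware augmentations, the enhanced loss and the alignment term.
   Slices are processed one at a time per epoch; each loss component
   backpropagates into the shared accumulated gradients and a single
   optimizer step is taken per epoch. The full-graph embedding computed for
   the spatial term is reused by the triplet terms of the same epoch. A
   non-finite loss raises immediately with the epoch and component.

7. **Denoising** (`denoise`). A two-layer perceptron mirroring the encoder
   (h → 2h with PReLU → m) is fitted on the frozen embeddings by mean
   squared reconstruction error summed over slices (L1 available); 500
   epochs at learning rate 1e-3 by default.

8. **Metrics** (`metrics`). Batch entropy uses 30-nearest-neighbor regions;
   regional batch proportions are divided by total batch sizes,
   renormalized, scored with positive Shannon entropy and the mean is
   divided by log(#batches) so the score lies in [0, 1]. cASW rescales
   label silhouettes to [0, 1]; bASW = mean(1 − |s|) on batch silhouettes
   so perfect mixing scores 1. LISI uses a perplexity-calibrated Gaussian
   kernel (perplexity 30, 3·perplexity neighbors, binary search on the
   bandwidth) and the inverse Simpson index of neighborhood category
   probabilities; bLISI = median(x−1)/(B−1), cLISI = median(C−x)/(C−1) with
   B batches and C label categories. Graph connectivity averages the
   largest-connected-component fraction of each label's kNN subgraph
   (k = 15). `leiden_at_k` sweeps the Leiden resolution and returns the
   partition whose cluster count is closest to a known domain count, the
   usual workflow when the number of anatomical domains is known; `gmm`
   offers an mclust-style Gaussian-mixture alternative recommended for
   Visium-like data.

## Numerical and implementation choices

- **Autodiff engine.** All training runs on a compact reverse-mode engine
  over numpy arrays written for this package. Leaf gradients accumulate
  across multiple backward calls (intermediate gradients live only in a
  per-call table), which implements the per-slice gradient accumulation
  directly. Every primitive and each composite loss is validated against
  central finite differences in the test suite. The two O(n²) losses
  (InfoNCE and the spatial regularizer) are fused graph nodes with
  closed-form vector-Jacobian products (softmax-minus-indicator and
  pairwise-distance chain rules respectively), keeping large temporaries
  and Python overhead out of the training loop; training tensors are
  float32.
- Cosine similarities use an 1e-8 norm guard; pairwise distances an 1e-12
  guard under the square root. The InfoNCE softmax is row-max stabilized.
- Min-max normalizations inside losses are differentiated exactly
  (subgradients at the arg-extrema).
- Exact-tie edge lengths (L = 2r) are included in the spatial graph.
- Leiden is seeded explicitly; Louvain seeds Python's `random` module,
  which igraph uses as its RNG source.
- Community detection with no edges yields a single community with a
  warning; community strength on an edgeless graph raises.

## Synthetic data

`synthetic.simulate_slices` emulates the layered tissue the method targets:
spots on jittered lattices over one footprint (per-slice spacing sets the
resolution; the defaults 1.0 and 1.4 give ≈1,580 and ≈790 spots, a 2×
density difference), five horizontal band domains (so domain adjacency is
linear, like cortical layers), 300 genes of which each domain elevates 10
markers by e^1.5 over a baseline of 0.5, a gene-wise multiplicative
lognormal batch factor with σ = 0.8 per slice (a strong, platform-like
shift), an optional per-slice depth factor, and negative binomial counts
(gamma–Poisson, dispersion 0.5; a Gaussian option exists for fast unit
tests). The same seed reproduces every array bit-for-bit.

What the simulation does *not* emulate: spatial autocorrelation within
domains beyond the shared mean, curved or branched domain geometry,
cell-type mixtures within spots, platform-specific dropout patterns, and
segmentation artifacts. Passing the synthetic benchmark therefore shows the
machinery removes per-gene batch shifts while preserving band-shaped
domains; it does not certify performance on any particular real platform
pairing.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` run the headline experiment at
two slices of ≈1,580/790 spots × 300 genes with 500 total epochs (stage 1 =
100) and MNN refresh every 100 epochs — sizes chosen so a complete run
takes a few minutes on one CPU core while leaving the qualitative behaviour
of the full-scale schedule intact. The training-sanity loop uses one slice
of 800 spots × 200 genes for 200 stage-2 epochs; self-alignment integrates
two copies of the ≈790-spot slice for 200 epochs.

## Known limitations

- A contrastive loss over all spot pairs is O(n²) per slice per epoch;
  slices beyond ~10⁴ spots become slow on one core. (The full 2000-epoch
  schedule is the package default; the benchmark uses the reduced schedule
  above.)
- With temperature τ = 0.5 the InfoNCE loss has a floor of roughly
  log(2n − 2 + e^{1/τ}) − 1/τ because n ≫ h unit vectors cannot be mutually
  anti-correlated (their mean pairwise cosine is ≥ −1/(n−1)). On 800 spots
  this caps the attainable relative decrease of the stage-2 contrastive
  loss at ~27%; larger decreases require a smaller temperature, which in
  our experiments degraded cross-slice mixing on some seeds. The package
  therefore keeps τ = 0.5 and reports the loss decrease as measured.
- Denoising operates in log-normalized space with a Gaussian
  reconstruction error; no count-model (negative binomial) likelihood.
- No coordinate-system registration (the embedding aligns expression
  programs, not physical coordinates), no histology-image inputs, no
  semi-supervised use of annotations.
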