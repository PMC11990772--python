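# tacos

Community-enhanced graph contrastive learning for integrating multiple
spatial transcriptomics slices.

## The problem

Spatial transcriptomics experiments produce *slices*: spots-by-genes
expression matrices in which every spot also carries a 2-D tissue
coordinate. Slices from different platforms (10x Visium, Slide-seqV2,
Stereo-seq, seqFISH, Xenium), donors or conditions differ in spot density
("resolution") and carry systematic non-biological expression differences
(batch effects). Joint analysis needs a shared low-dimensional embedding in
which slices are well mixed but real spatial domains — contiguous tissue
regions with a common expression program, such as cortical layers — remain
separable.

`tacos` builds that embedding. For each slice it constructs an
alpha-complex-style spatial neighbor graph from the coordinates, then
trains a shared two-layer graph-convolutional encoder with a contrastive
objective between two augmented graph views. The augmentations are
*community-aware*: Leiden communities are detected on the graph, each
community c gets a strength score

    S_c = E_c/|E| − (Σ_{v∈c} d_v)² / (4|E|²)

(its modularity contribution), and genes/edges are masked with
probabilities weighted by these strengths, so views preserve community
cores and perturb the periphery. The contrastive InfoNCE loss additionally
receives a ramped similarity bonus γ_k (H_i + H_j)·S for pairs in strong
communities. A spatial regularizer Σ_ij D^s_ij (1 − D^Z_ij)/n² keeps
embedding distances faithful to tissue distances, and a triplet hinge loss
over mutual-nearest-neighbor (MNN) pairs across slices removes batch
effects:

    L = Σ_t L_t + α Σ_t L_within^t + β Σ_{t1<t2} L_across^{t1,t2}

A small symmetric decoder maps embeddings back to expression space for
denoising, and the package ships the standard integration metrics (batch
entropy, cASW/bASW, cLISI/bLISI, graph connectivity) plus Leiden/Louvain/
Gaussian-mixture clustering for spatial-domain identification.

All training runs on a compact reverse-mode autodiff engine over numpy that
is part of the package (gradient-checked against finite differences), so
the only heavyweight dependencies are the scientific Python stack, igraph
and anndata.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from tacos import (SimConfig, simulate_slices, preprocess, integrate,
                   IntegrationConfig, batch_entropy)
from tacos.metrics import leiden_at_k

# two simulated slices of one layered tissue: 5 domains, 300 genes,
# strong gene-wise batch shift, 2x differing spot density
sim = simulate_slices(SimConfig(seed=0))
slices = [preprocess(s) for s in sim.slices]
print([s.n_spots for s in slices])          # [1581, 792]

res = integrate(slices, IntegrationConfig(epochs=500, stage1_epochs=100, seed=0))
Z, batch = res.concatenated()

truth = np.concatenate(sim.labels)
labels = leiden_at_k(Z, n_clusters=5, seed=0)
print(round(batch_entropy(Z, batch), 3))                   # 0.828
print(round(adjusted_rand_score(truth, labels), 3))        # 0.911
```

The two printed numbers summarize the integration: normalized batch
entropy 0.828 means the two slices are almost perfectly interleaved in the
embedding (1 = ideal mixing; the unintegrated joint PCA space of the same
data scores 0.0), while the adjusted Rand index of 0.911 between Leiden
clusters of the embedding and the true simulated domains shows the five
tissue layers survived integration nearly intact.

A command-line interface wraps the same pipeline:

```bash
tacos simulate --out-dir fixtures/ --seed 0
tacos integrate --inputs fixtures/sim0.h5ad --inputs fixtures/sim1.h5ad \
      --out integrated.h5ad --log-tsv losses.tsv
tacos metrics  --embeddings integrated.h5ad --out report.json
tacos denoise  --embeddings integrated.h5ad --out denoised.h5ad
```

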