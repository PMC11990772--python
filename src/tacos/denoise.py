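"""Expression denoising: decode embeddings back to gene space.

A two-layer perceptron mirroring the encoder (h -> 2h with PReLU -> m) is
fitted to reconstruct the log-normalized expression from the frozen
integration embeddings by minimizing the reconstruction error summed over
slices (mean squared error by default; L1 available). Because the
embeddings aggregate each spot's spatial neighborhood, the reconstruction
smooths technical dropout while preserving domain-specific expression
patterns.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Adam, Tensor, as_tensor, prelu


class MLPDecoder:
    """Two-layer perceptron: h -> 2h (PReLU) -> m, symmetric to the encoder."""

    def __init__(self, h: int, n_genes: int, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        h2 = 2 * h

        def glorot(fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)

        self.h = int(h)
        self.n_genes = int(n_genes)
        self.W1 = Tensor(glorot(h, h2), requires_grad=True)
        self.b1 = Tensor(np.zeros(h2, dtype=dtype), requires_grad=True)
        self.slope = Tensor(np.asarray(0.25, dtype=dtype), requires_grad=True)
        self.W2 = Tensor(glorot(h2, n_genes), requires_grad=True)
        self.b2 = Tensor(np.zeros(n_genes, dtype=dtype), requires_grad=True)

    def parameters(self):
        return [self.W1, self.b1, self.slope, self.W2, self.b2]

    def forward(self, Z) -> Tensor:
        Z = as_tensor(np.asarray(Z, dtype=self.W1.dtype) if not isinstance(Z, Tensor) else Z)
        if Z.shape[1] != self.h:
            raise ValueError(f"embedding dimension {Z.shape[1]} != decoder h={self.h}")
        H = prelu(Z @ self.W1 + self.b1, self.slope)
        return H @ self.W2 + self.b2


def fit_decoder(
    Z_all: list,
    X_all: list,
    epochs: int = 500,
    lr: float = 1e-3,
    seed: int = 0,
    loss: str = "mse",
):
    """Fit the decoder on frozen embeddings.

    Parameters
    ----------
    Z_all, X_all : lists of per-slice embedding and normalized expression
        matrices with matching row counts.
    loss : {"mse", "l1"}
        Reconstruction norm.

    Returns
    -------
    decoder : MLPDecoder
    history : list of float
        Total reconstruction loss per epoch (index 0 = initialization).
    """
    if len(Z_all) != len(X_all) or not Z_all:
        raise ValueError("need matching, nonempty lists of embeddings and matrices")
    Z_all = [np.asarray(Z, dtype=np.float32) for Z in Z_all]
    X_all = [np.asarray(X, dtype=np.float32) for X in X_all]
    h = Z_all[0].shape[1]
    m = X_all[0].shape[1]
    for Z, X in zip(Z_all, X_all):
        if Z.shape[0] != X.shape[0]:
            raise ValueError("embedding and expression row counts differ")
        if Z.shape[1] != h or X.shape[1] != m:
            raise ValueError("inconsistent dimensions across slices")
    if loss not in ("mse", "l1"):
        raise ValueError("loss must be 'mse' or 'l1'")

    decoder = MLPDecoder(h, m, seed=seed)
    optimizer = Adam(decoder.parameters(), lr=lr)

    def total_loss() -> Tensor:
        acc = None
        for Z, X in zip(Z_all, X_all):
            R = decoder.forward(Z) - Tensor(X)
            if loss == "mse":
                term = (R * R).mean()
            else:
                term = ((R * R) + 1e-12).sqrt().mean()  # smooth L1 surrogate
            acc = term if acc is None else acc + term
        return acc

    history = [total_loss().item()]
    for _ in range(epochs):
        L = total_loss()
        L.backward()
        optimizer.step()
        optimizer.zero_grad()
        history.append(L.item())
    return decoder, history


def denoise(Z: np.ndarray, decoder: MLPDecoder) -> np.ndarray:
    """Deterministically map embeddings back to expression space."""
    return decoder.forward(np.asarray(Z)).data.astype(np.float64)
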