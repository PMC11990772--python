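"""Reading, writing and preprocessing of spatial transcriptomics slices.

A :class:`Slice` bundles a spots x genes expression matrix, per-spot 2-D
coordinates, identifiers and optional annotations. Slices can be read from
h5ad (AnnData), a MatrixMarket directory (CellRanger-style triplet plus a
coordinate table) or delimited text, and are preprocessed with the standard
workflow: per-spot total-count normalization to a fixed target, natural
log1p transform, and selection of the shared highly variable genes across
slices with a variance-stabilized (seurat_v3-style) ranking computed on raw
counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import (
    CoordinateMissingError,
    DuplicateIdentifierError,
    EmptyGeneSetError,
)

logger = logging.getLogger(__name__)

RAW = "raw"
NORMALIZED = "normalized"
LOG_NORMALIZED = "log_normalized"
_STATES = (RAW, NORMALIZED, LOG_NORMALIZED)


@dataclass
class Slice:
    """One spatial transcriptomics sample.

    Attributes
    ----------
    spot_ids : list of str
        Unique spot (capture location) identifiers, row order of ``X``.
    gene_ids : list of str
        Unique gene identifiers, column order of ``X``.
    X : ndarray, spots x genes
        Expression matrix; raw counts or normalized values depending on
        ``processing``.
    coords : ndarray, spots x 2
        Spatial coordinates of each spot.
    slice_id : str
        Name of the slice (sample).
    labels : ndarray of str, optional
        Per-spot annotations (e.g. cortical layer).
    processing : str
        One of ``raw``, ``normalized``, ``log_normalized``.
    """

    spot_ids: list
    gene_ids: list
    X: np.ndarray
    coords: np.ndarray
    slice_id: str = "slice"
    labels: np.ndarray | None = None
    processing: str = RAW

    def __post_init__(self):
        self.X = np.asarray(self.X)
        if sp.issparse(self.X):  # pragma: no cover - defensive
            self.X = self.X.toarray()
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_spots(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def validate(self):
        if self.processing not in _STATES:
            raise ValueError(f"unknown processing state {self.processing!r}")
        n, m = self.X.shape
        if len(self.spot_ids) != n or self.coords.shape != (n, 2):
            raise ValueError(
                f"slice {self.slice_id!r}: X has {n} rows but "
                f"{len(self.spot_ids)} spot ids / coords shape {self.coords.shape}"
            )
        if len(self.gene_ids) != m:
            raise ValueError(
                f"slice {self.slice_id!r}: X has {m} columns but "
                f"{len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != m:
            raise DuplicateIdentifierError(
                f"slice {self.slice_id!r} has duplicate gene identifiers"
            )
        if len(set(self.spot_ids)) != n:
            raise DuplicateIdentifierError(
                f"slice {self.slice_id!r} has duplicate spot identifiers"
            )
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match number of spots")
        if not np.all(np.isfinite(self.X)):
            raise ValueError(f"slice {self.slice_id!r}: X has non-finite entries")
        if self.processing != LOG_NORMALIZED and np.any(self.X < 0):
            raise ValueError(f"slice {self.slice_id!r}: negative expression values")

    # ------------------------------------------------------------------
    def to_anndata(self) -> ad.AnnData:
        obs = pd.DataFrame(index=pd.Index(self.spot_ids, name="spot_id"))
        if self.labels is not None:
            obs["label"] = pd.Categorical(self.labels)
        adata = ad.AnnData(
            X=np.asarray(self.X, dtype=np.float32),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.obsm["spatial"] = np.asarray(self.coords, dtype=float)
        adata.uns["slice_id"] = self.slice_id
        adata.uns["processing"] = self.processing
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, slice_id: str | None = None) -> "Slice":
        if "spatial" not in adata.obsm:
            raise CoordinateMissingError(
                "no 'spatial' array in .obsm; spatial coordinates are required"
            )
        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        X = np.asarray(X)
        if not np.issubdtype(X.dtype, np.number):
            raise ValueError("expression matrix is not numeric")
        labels = None
        if "label" in adata.obs:
            labels = np.asarray(adata.obs["label"].astype(str))
        return cls(
            spot_ids=list(map(str, adata.obs_names)),
            gene_ids=list(map(str, adata.var_names)),
            X=X.astype(np.float64),
            coords=np.asarray(adata.obsm["spatial"], dtype=float)[:, :2],
            slice_id=str(slice_id or adata.uns.get("slice_id", "slice")),
            labels=labels,
            processing=str(adata.uns.get("processing", RAW)),
        )

    def write_h5ad(self, path):
        self.to_anndata().write_h5ad(Path(path))


# ----------------------------------------------------------------------
# loading
# ----------------------------------------------------------------------

def load_slice(path, format: str, coords_path=None, slice_id: str | None = None) -> Slice:
    """Load one slice from disk.

    Parameters
    ----------
    path : str or Path
        File (h5ad, csv) or directory (mtx_dir) to read.
    format : {"h5ad", "mtx_dir", "csv"}
        Declared on-disk layout.
    coords_path : str or Path, optional
        Sidecar coordinate CSV (columns ``spot_id,x,y``) for the ``csv``
        format; defaults to ``<stem>_coords.csv`` next to the expression file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "h5ad":
        return Slice.from_anndata(ad.read_h5ad(path), slice_id=slice_id)
    if format == "mtx_dir":
        return _load_mtx_dir(path, slice_id=slice_id)
    if format == "csv":
        return _load_csv(path, coords_path=coords_path, slice_id=slice_id)
    raise ValueError(f"unknown format {format!r}")


def _read_coords_table(coords_file: Path, spot_ids: list) -> np.ndarray:
    df = pd.read_csv(coords_file)
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise CoordinateMissingError(
            f"{coords_file} must have columns spot_id,x,y (found {list(df.columns)})"
        )
    df = df.set_index(df["spot_id"].astype(str))
    missing = [s for s in spot_ids if s not in df.index]
    if missing:
        raise CoordinateMissingError(
            f"{coords_file} lacks coordinates for {len(missing)} spots "
            f"(e.g. {missing[:3]})"
        )
    return df.loc[spot_ids, ["x", "y"]].to_numpy(dtype=float)


def _load_mtx_dir(path: Path, slice_id=None) -> Slice:
    def _first(*names):
        for name in names:
            p = path / name
            if p.exists():
                return p
        raise FileNotFoundError(f"none of {names} found in {path}")

    mtx = scipy.io.mmread(_first("matrix.mtx", "matrix.mtx.gz"))
    genes_file = _first("genes.tsv", "features.tsv")
    genes = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = (
        pd.read_csv(_first("barcodes.tsv"), sep="\t", header=None)[0].astype(str).tolist()
    )
    X = np.asarray(sp.csr_matrix(mtx).todense(), dtype=float)
    # CellRanger convention: rows = genes, columns = barcodes
    if X.shape == (len(genes), len(barcodes)):
        X = X.T
    elif X.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {X.shape} matches neither (genes, spots) nor (spots, genes)"
        )
    coords_file = path / "coords.csv"
    if not coords_file.exists():
        raise CoordinateMissingError(f"{coords_file} not found")
    coords = _read_coords_table(coords_file, barcodes)
    return Slice(
        spot_ids=barcodes,
        gene_ids=genes,
        X=X,
        coords=coords,
        slice_id=str(slice_id or path.name),
    )


def _load_csv(path: Path, coords_path=None, slice_id=None) -> Slice:
    df = pd.read_csv(path, index_col=0)
    try:
        X = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from exc
    spot_ids = df.index.astype(str).tolist()
    gene_ids = df.columns.astype(str).tolist()
    if coords_path is None:
        coords_path = path.with_name(path.stem + "_coords.csv")
    coords_path = Path(coords_path)
    if not coords_path.exists():
        raise CoordinateMissingError(f"coordinate table {coords_path} not found")
    coords = _read_coords_table(coords_path, spot_ids)
    return Slice(
        spot_ids=spot_ids,
        gene_ids=gene_ids,
        X=X,
        coords=coords,
        slice_id=str(slice_id or path.stem),
    )


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------

def preprocess(slice_: Slice, scale_total: float = 10_000.0) -> Slice:
    """Total-count normalize each spot to ``scale_total`` and log1p transform.

    Each spot's counts are divided by its total and multiplied by
    ``scale_total``, then ``ln(1 + x)`` is applied. Spots with zero total
    count are kept as all-zero rows (dropping them would desynchronize the
    coordinate table); a warning is emitted.
    """
    if slice_.processing != RAW:
        raise ValueError(
            f"preprocess expects a raw slice; got state {slice_.processing!r} "
            "(refusing to double-transform)"
        )
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    totals = slice_.X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"slice {slice_.slice_id!r}: {int(zero.sum())} spot(s) with zero total "
            "count kept as all-zero rows",
            stacklevel=2,
        )
    safe_totals = np.where(zero, 1.0, totals)
    X = slice_.X / safe_totals[:, None] * scale_total
    X = np.log1p(X)
    return replace(slice_, X=X, processing=LOG_NORMALIZED)


# ----------------------------------------------------------------------
# highly variable genes
# ----------------------------------------------------------------------

def seurat_v3_variance(X: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Variance-stabilized variance per gene (seurat_v3-style ranking score).

    Fits a lowess trend of log10 variance against log10 mean on raw counts,
    standardizes each gene by the trend-expected standard deviation with
    values clipped at sqrt(n), and returns the variance of the standardized
    values. Higher means more variable than expected for its mean.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    mu = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n > 1 else np.zeros(X.shape[1])
    score = np.zeros(X.shape[1])
    ok = (mu > 0) & (var > 0)
    if not ok.any():
        return score
    log_mu = np.log10(mu[ok])
    log_var = np.log10(var[ok])
    if ok.sum() >= 10 and np.unique(log_mu).size >= 5:
        fitted = lowess(log_var, log_mu, frac=span, return_sorted=False)
    else:
        # too few genes for a stable local fit: quadratic trend instead
        deg = min(2, np.unique(log_mu).size - 1)
        coef = np.polyfit(log_mu, log_var, deg=max(deg, 0))
        fitted = np.polyval(coef, log_mu)
    exp_sd = np.sqrt(10.0 ** fitted)
    clip_val = np.sqrt(n)
    Z = (X[:, ok] - mu[ok]) / exp_sd
    np.clip(Z, -clip_val, clip_val, out=Z)
    score[ok] = Z.var(axis=0, ddof=1)
    return score


def hvg_set(slice_: Slice, n_top: int = 3000) -> list:
    """Per-slice HVG set: all genes if the slice has fewer than ``n_top``
    genes, otherwise the ``n_top`` genes by variance-stabilized ranking."""
    if slice_.n_genes < n_top:
        return list(slice_.gene_ids)
    if slice_.processing != RAW:
        warnings.warn(
            "variance-stabilized HVG ranking is defined on raw counts; "
            f"slice {slice_.slice_id!r} is {slice_.processing}",
            stacklevel=2,
        )
    score = seurat_v3_variance(slice_.X)
    order = np.argsort(-score, kind="stable")[:n_top]
    return [slice_.gene_ids[i] for i in order]


def select_shared_hvgs(slices: list, n_top: int = 3000):
    """Subset all slices to the intersection of their per-slice HVG sets.

    Returns the subset slices (identical, lexicographically ordered gene
    columns) and the shared gene list.
    """
    if len(slices) < 2:
        raise ValueError("select_shared_hvgs needs at least two slices")
    sets = [set(hvg_set(s, n_top=n_top)) for s in slices]
    shared = set.intersection(*sets)
    if not shared:
        ids = ", ".join(repr(s.slice_id) for s in slices)
        raise EmptyGeneSetError(
            f"intersection of highly variable gene sets is empty across slices: {ids}"
        )
    genes = sorted(shared)
    out = []
    for s in slices:
        col = {g: i for i, g in enumerate(s.gene_ids)}
        idx = np.array([col[g] for g in genes], dtype=int)
        out.append(replace(s, X=s.X[:, idx], gene_ids=list(genes)))
    logger.info("shared HVG selection kept %d genes across %d slices", len(genes), len(slices))
    return out, genes
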