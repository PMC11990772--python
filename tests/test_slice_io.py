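"""Slice loading, preprocessing and shared HVG selection."""

import numpy as np
import pytest
import scipy.io
import scipy.sparse as sp

from tacos.errors import CoordinateMissingError, DuplicateIdentifierError, EmptyGeneSetError
from tacos.slice_io import (
    LOG_NORMALIZED,
    RAW,
    Slice,
    hvg_set,
    load_slice,
    preprocess,
    select_shared_hvgs,
    seurat_v3_variance,
)


@pytest.fixture
def arrays():
    rng = np.random.default_rng(1)
    X = rng.poisson(4.0, size=(10, 5)).astype(float)
    coords = rng.uniform(0, 8, size=(10, 2))
    spots = [f"b{i}" for i in range(10)]
    genes = [f"g{j}" for j in range(5)]
    return X, coords, spots, genes


def _write_h5ad(tmp_path, X, coords, spots, genes, name="s.h5ad"):
    s = Slice(spot_ids=spots, gene_ids=genes, X=X, coords=coords, slice_id="fix")
    path = tmp_path / name
    s.write_h5ad(path)
    return path


def _write_mtx_dir(tmp_path, X, coords, spots, genes):
    d = tmp_path / "mtx"
    d.mkdir()
    scipy.io.mmwrite(d / "matrix.mtx", sp.coo_matrix(X.T))  # genes x spots
    (d / "genes.tsv").write_text("".join(f"{g}\tname_{g}\n" for g in genes))
    (d / "barcodes.tsv").write_text("".join(f"{b}\n" for b in spots))
    lines = ["spot_id,x,y"] + [f"{b},{x},{y}" for b, (x, y) in zip(spots, coords)]
    (d / "coords.csv").write_text("\n".join(lines) + "\n")
    return d


def test_h5ad_roundtrip(tmp_path, arrays):
    X, coords, spots, genes = arrays
    s = load_slice(_write_h5ad(tmp_path, X, coords, spots, genes), format="h5ad")
    assert s.processing == RAW
    assert s.spot_ids == spots and s.gene_ids == genes
    np.testing.assert_allclose(s.X, X)
    np.testing.assert_allclose(s.coords, coords)


def test_mtx_dir_equivalent_to_h5ad(tmp_path, arrays):
    X, coords, spots, genes = arrays
    a = load_slice(_write_h5ad(tmp_path, X, coords, spots, genes), format="h5ad")
    b = load_slice(_write_mtx_dir(tmp_path, X, coords, spots, genes), format="mtx_dir")
    assert a.spot_ids == b.spot_ids and a.gene_ids == b.gene_ids
    np.testing.assert_allclose(a.X, b.X)
    np.testing.assert_allclose(a.coords, b.coords)


def test_csv_loader(tmp_path, arrays):
    import pandas as pd

    X, coords, spots, genes = arrays
    expr = tmp_path / "expr.csv"
    pd.DataFrame(X, index=spots, columns=genes).to_csv(expr)
    pd.DataFrame({"spot_id": spots, "x": coords[:, 0], "y": coords[:, 1]}).to_csv(
        tmp_path / "expr_coords.csv", index=False
    )
    s = load_slice(expr, format="csv")
    np.testing.assert_allclose(s.X, X)
    np.testing.assert_allclose(s.coords, coords)


def test_missing_coordinates_raises(tmp_path, arrays):
    import anndata as ad
    import pandas as pd

    X, coords, spots, genes = arrays
    adata = ad.AnnData(
        X=X.astype(np.float32),
        obs=pd.DataFrame(index=spots),
        var=pd.DataFrame(index=genes),
    )
    path = tmp_path / "nocoords.h5ad"
    adata.write_h5ad(path)
    with pytest.raises(CoordinateMissingError):
        load_slice(path, format="h5ad")


def test_duplicate_gene_ids_raise(arrays):
    X, coords, spots, genes = arrays
    genes = list(genes)
    genes[1] = genes[0]
    with pytest.raises(DuplicateIdentifierError):
        Slice(spot_ids=spots, gene_ids=genes, X=X, coords=coords)


def test_preprocess_formula_and_guards(arrays):
    X, coords, spots, genes = arrays
    # spot 0: one gene with count 5 out of total 5000
    X = np.zeros((3, 2))
    X[0] = [5, 4995]
    X[1] = [10000, 0]  # already sums to the scale target
    s = Slice(spot_ids=["a", "b", "c"], gene_ids=["g1", "g2"], X=X,
              coords=np.zeros((3, 2)) + np.arange(3)[:, None])
    with pytest.warns(UserWarning, match="zero total"):
        out = preprocess(s)
    assert out.processing == LOG_NORMALIZED
    assert np.isclose(out.X[0, 0], np.log(11.0), atol=1e-12)  # 5/5000*1e4 -> ln(11)
    np.testing.assert_allclose(out.X[1], np.log1p([10000.0, 0.0]))
    np.testing.assert_allclose(out.X[2], 0.0)  # zero spot kept as zeros
    with pytest.raises(ValueError, match="raw"):
        preprocess(out)  # idempotence guard


def test_normalized_row_sums(arrays):
    X, coords, spots, genes = arrays
    s = Slice(spot_ids=spots, gene_ids=genes, X=X, coords=coords)
    out = preprocess(s)
    sums = np.expm1(out.X).sum(axis=1)
    np.testing.assert_allclose(sums, 10_000.0, rtol=1e-6)


def test_hvg_all_genes_when_below_threshold(arrays):
    X, coords, spots, genes = arrays
    s = Slice(spot_ids=spots, gene_ids=genes, X=X, coords=coords)
    assert hvg_set(s, n_top=3000) == genes


def test_hvg_ranking_finds_structured_genes():
    """Genes with domain-structured means rank above flat noise genes."""
    rng = np.random.default_rng(7)
    n, m, k = 400, 500, 10
    base = rng.lognormal(mean=1.0, sigma=0.6, size=m)  # spread of flat baselines
    mu = np.tile(base, (n, 1))
    domain = (np.arange(n) // (n // 4)).clip(0, 3)
    for g in range(k):  # structured genes 0..9: strong domain elevation
        mu[domain == (g % 4), g] *= 8.0
    X = rng.poisson(mu).astype(float)
    score = seurat_v3_variance(X)
    top10 = set(np.argsort(-score)[:k])
    assert top10 == set(range(k))


def test_shared_hvg_intersection_and_order():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 5, size=(6, 2))

    def mk(genes, sid):
        X = rng.poisson(3.0, size=(6, len(genes))).astype(float)
        return Slice(spot_ids=[f"{sid}{i}" for i in range(6)], gene_ids=genes,
                     X=X, coords=coords, slice_id=sid)

    a = mk(["g3", "g1", "g2"], "a")
    b = mk(["g2", "g4", "g3"], "b")
    out, shared = select_shared_hvgs([a, b], n_top=3000)
    assert shared == ["g2", "g3"]  # intersection, lexicographic
    assert out[0].gene_ids == out[1].gene_ids == shared
    # column content follows the gene ids
    np.testing.assert_allclose(out[0].X[:, 0], a.X[:, 2])
    np.testing.assert_allclose(out[0].X[:, 1], a.X[:, 0])


def test_empty_intersection_raises():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 5, size=(4, 2))

    def mk(genes, sid):
        return Slice(spot_ids=[f"{sid}{i}" for i in range(4)], gene_ids=genes,
                     X=rng.poisson(2.0, size=(4, len(genes))).astype(float),
                     coords=coords, slice_id=sid)

    with pytest.raises(EmptyGeneSetError, match="a.*b"):
        select_shared_hvgs([mk(["g1"], "a"), mk(["g2"], "b")])
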