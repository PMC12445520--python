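"""Reading and writing count matrices, metadata and annotation.

The on-disk layout follows droplet-platform conventions: a MatrixMarket
triplet (``matrix.mtx`` genes x cells, ``features.tsv``, ``barcodes.tsv``)
or a dense TSV (genes in rows, cells in columns), plus a cell-metadata TSV
(barcode, sample_id, genotype, cell_type) and a gene-annotation TSV
(gene_id, chromosome, class). In memory everything is an
:class:`anndata.AnnData` with cells as observations.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class CountMatrixError(ValueError):
    """Raised for malformed or mutually inconsistent count-matrix inputs."""


def _check_unique(values, what: str) -> None:
    s = pd.Series(values)
    if s.duplicated().any():
        dupes = s[s.duplicated()].unique()[:5]
        raise CountMatrixError(f"duplicate {what}: {list(dupes)}")


def read_counts(
    mtx_path=None,
    features_path=None,
    barcodes_path=None,
    dense_tsv_path=None,
) -> ad.AnnData:
    """Read a counts matrix from a MatrixMarket triplet or a dense TSV.

    Returns cells x genes AnnData with integer counts; gene and cell order
    is preserved from the input. Raises :class:`CountMatrixError` on
    dimension mismatches, non-integer entries, or duplicate identifiers.
    """
    if dense_tsv_path is not None:
        with open(dense_tsv_path) as fh:  # pandas mangles duplicate columns
            header = fh.readline().rstrip("\n").split("\t")
        _check_unique(header[1:], "barcode")
        df = pd.read_csv(dense_tsv_path, sep="\t", index_col=0)
        _check_unique(df.index, "gene_id")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise CountMatrixError(f"non-integer entries in {dense_tsv_path}")
            values = values.astype(np.int64)
        X = sparse.csr_matrix(values.T)
        genes = df.index.astype(str)
        barcodes = df.columns.astype(str)
    else:
        if mtx_path is None or features_path is None or barcodes_path is None:
            raise CountMatrixError(
                "need either dense_tsv_path or all of mtx/features/barcodes paths"
            )
        for p in (mtx_path, features_path, barcodes_path):
            if not Path(p).exists():
                raise CountMatrixError(f"missing input file: {p}")
        try:
            mat = spio.mmread(str(mtx_path))
        except ValueError as e:
            raise CountMatrixError(f"malformed MatrixMarket file {mtx_path}: {e}") from e
        feats = pd.read_csv(features_path, sep="\t", header=None)
        bcs = pd.read_csv(barcodes_path, sep="\t", header=None)
        genes = feats.iloc[:, 0].astype(str)
        barcodes = bcs.iloc[:, 0].astype(str)
        _check_unique(genes, "gene_id")
        _check_unique(barcodes, "barcode")
        if mat.shape != (len(genes), len(barcodes)):
            raise CountMatrixError(
                f"dimension mismatch: matrix {mat.shape} vs "
                f"{len(genes)} features x {len(barcodes)} barcodes"
            )
        data = mat.data if sparse.issparse(mat) else np.asarray(mat)
        if not np.allclose(data, np.round(data)):
            raise CountMatrixError(f"non-integer entries in {mtx_path}")
        X = sparse.csr_matrix(mat.T).astype(np.int64)
    if X.min() < 0:
        raise CountMatrixError("negative counts")
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    adata.var["gene_id"] = adata.var.index
    return adata


def attach_metadata(adata: ad.AnnData, cell_meta: pd.DataFrame, gene_anno: pd.DataFrame):
    """Join cell metadata and gene annotation onto an AnnData in place.

    ``cell_meta`` needs columns barcode/sample_id/genotype/cell_type;
    ``gene_anno`` needs gene_id/chromosome (and optionally class). Every
    sample must map to exactly one genotype.
    """
    cm = cell_meta.set_index("barcode") if "barcode" in cell_meta else cell_meta
    missing = adata.obs.index.difference(cm.index)
    if len(missing):
        raise CountMatrixError(f"{len(missing)} barcodes lack metadata, e.g. {missing[0]}")
    for col in ("sample_id", "genotype", "cell_type"):
        adata.obs[col] = cm.loc[adata.obs.index, col].to_numpy()
    per_sample = adata.obs.groupby("sample_id", observed=True)["genotype"].nunique()
    if (per_sample > 1).any():
        bad = per_sample[per_sample > 1].index.tolist()
        raise CountMatrixError(f"samples with more than one genotype: {bad}")
    ga = gene_anno.set_index("gene_id") if gene_anno.index.name != "gene_id" else gene_anno
    missing_g = adata.var.index.difference(ga.index)
    if len(missing_g):
        raise CountMatrixError(f"{len(missing_g)} genes lack annotation")
    adata.var["chromosome"] = ga.loc[adata.var.index, "chromosome"].to_numpy()
    if "class" in ga.columns:
        adata.var["class"] = ga.loc[adata.var.index, "class"].to_numpy()
    return adata


def write_counts(adata: ad.AnnData, outdir) -> None:
    """Write MatrixMarket triplet + metadata/annotation TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sparse.csr_matrix(adata.X)
    spio.mmwrite(str(outdir / "matrix.mtx"), X.T.astype(np.int64))
    pd.Series(adata.var.index).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs.index).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    cols = [c for c in ("sample_id", "genotype", "cell_type") if c in adata.obs]
    meta = adata.obs[cols].copy()
    meta.insert(0, "barcode", adata.obs.index)
    meta.to_csv(outdir / "cell_metadata.tsv", sep="\t", index=False)
    anno_cols = [c for c in ("chromosome", "class") if c in adata.var]
    anno = adata.var[anno_cols].copy()
    anno.insert(0, "gene_id", adata.var.index)
    anno.to_csv(outdir / "gene_annotation.tsv", sep="\t", index=False)


def read_dataset(indir) -> ad.AnnData:
    """Read a directory written by :func:`write_counts`."""
    indir = Path(indir)
    adata = read_counts(
        mtx_path=indir / "matrix.mtx",
        features_path=indir / "features.tsv",
        barcodes_path=indir / "barcodes.tsv",
    )
    meta = pd.read_csv(indir / "cell_metadata.tsv", sep="\t")
    anno = pd.read_csv(indir / "gene_annotation.tsv", sep="\t")
    return attach_metadata(adata, meta, anno)
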