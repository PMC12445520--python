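"""Cell and gene quality-control filters.

Cells are removed when they have fewer than 200 detected features or more
than 20% mitochondrial expression; genes are kept when expressed
(counts > 1) in at least three cells. Two notions of "expressed" coexist
deliberately: detection (count >= 1) for the per-cell feature tally, and
count > 1 for the biology-facing metrics, matching standard droplet QC
practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class QCThresholds:
    min_features: int = 200
    max_mito: float = 0.20
    min_cells_per_gene: int = 3
    expressed_min_count: int = 2  # "counts > 1"
    detection_min_count: int = 1  # feature detected
    filter_logic: str = "any"  # cell removed if ANY criterion fails (or "all")

    def __post_init__(self):
        if min(self.min_features, self.min_cells_per_gene) < 0 or self.max_mito < 0:
            raise ValueError("thresholds must be >= 0")
        if self.filter_logic not in ("any", "all"):
            raise ValueError("filter_logic must be 'any' or 'all'")


def _counts(adata: ad.AnnData):
    X = adata.X
    return X if sparse.issparse(X) else np.asarray(X)


def compute_mito_fraction(adata: ad.AnnData) -> np.ndarray:
    """Per-cell mitochondrial count fraction, stored in obs['mito_fraction'].

    Cells with zero total counts get fraction 0 and are flagged in
    obs['zero_total']. If no MT gene is annotated all fractions are 0 (with
    a warning).
    """
    X = _counts(adata)
    total = np.asarray(X.sum(axis=1)).ravel()
    is_mt = (adata.var["chromosome"] == "MT").to_numpy()
    if not is_mt.any():
        warnings.warn("no mitochondrial genes annotated; mito fractions set to 0")
        mito = np.zeros(adata.n_obs)
    else:
        mito = np.asarray(X[:, is_mt].sum(axis=1)).ravel()
    zero = total == 0
    if zero.any():
        warnings.warn(f"{zero.sum()} cells with zero total counts; fraction set to 0")
    frac = np.divide(mito, total, out=np.zeros_like(mito, dtype=float), where=~zero)
    adata.obs["mito_fraction"] = frac
    adata.obs["zero_total"] = zero
    return frac


def detected_features(adata: ad.AnnData, min_count: int = 1) -> np.ndarray:
    X = _counts(adata)
    if sparse.issparse(X):
        return np.asarray((X >= min_count).sum(axis=1)).ravel()
    return (X >= min_count).sum(axis=1)


def filter_cells(adata: ad.AnnData, thresholds: QCThresholds | None = None):
    """Apply the per-cell QC filter; returns (filtered AnnData, report).

    A cell is retained when it has at least ``min_features`` detected genes
    and at most ``max_mito`` mitochondrial fraction (strict inequalities on
    the removal side, so a cell at exactly 200 features and 20% mito stays).
    The report counts removals per sample and criterion.
    """
    t = thresholds or QCThresholds()
    if "mito_fraction" not in adata.obs:
        compute_mito_fraction(adata)
    nfeat = detected_features(adata, t.detection_min_count)
    adata.obs["n_features"] = nfeat
    fail_feat = nfeat < t.min_features
    fail_mito = adata.obs["mito_fraction"].to_numpy() > t.max_mito
    if t.filter_logic == "any":
        remove = fail_feat | fail_mito
    else:
        remove = fail_feat & fail_mito
    sample = (
        adata.obs["sample_id"]
        if "sample_id" in adata.obs
        else pd.Series("all", index=adata.obs.index)
    )
    report = (
        pd.DataFrame(
            {
                "sample_id": sample,
                "cells_in": 1,
                "fail_features": fail_feat.astype(int),
                "fail_mito": fail_mito.astype(int),
                "removed": remove.astype(int),
            }
        )
        .groupby("sample_id", observed=True)
        .sum()
        .reset_index()
    )
    if remove.all():
        raise ValueError(
            "all cells removed by QC: "
            f"{int(fail_feat.sum())} failed the feature rule, "
            f"{int(fail_mito.sum())} the mito rule"
        )
    return adata[~remove].copy(), report


def filter_genes(adata: ad.AnnData, thresholds: QCThresholds | None = None):
    """Keep genes expressed (count > 1) in at least ``min_cells_per_gene`` cells."""
    t = thresholds or QCThresholds()
    X = _counts(adata)
    if sparse.issparse(X):
        n_cells_expr = np.asarray((X >= t.expressed_min_count).sum(axis=0)).ravel()
    else:
        n_cells_expr = (X >= t.expressed_min_count).sum(axis=0)
    keep = n_cells_expr >= t.min_cells_per_gene
    return adata[:, keep].copy(), int((~keep).sum())


def run_qc(adata: ad.AnnData, thresholds: QCThresholds | None = None):
    """Cell filter then gene filter; returns (AnnData, cell report, n genes removed)."""
    filtered, report = filter_cells(adata, thresholds)
    filtered, n_genes_removed = filter_genes(filtered, thresholds)
    return filtered, report, n_genes_removed


class QCFilter(BaseEstimator, TransformerMixin):
    """scikit-learn-style transformer applying cell and gene QC to an AnnData.

    Parameters mirror :class:`QCThresholds`. ``fit`` records which cells and
    genes pass on the fitted data; ``transform`` subsets.
    """

    def __init__(
        self,
        min_features: int = 200,
        max_mito: float = 0.20,
        min_cells_per_gene: int = 3,
        expressed_min_count: int = 2,
        filter_logic: str = "any",
    ):
        self.min_features = min_features
        self.max_mito = max_mito
        self.min_cells_per_gene = min_cells_per_gene
        self.expressed_min_count = expressed_min_count
        self.filter_logic = filter_logic

    def _thresholds(self) -> QCThresholds:
        return QCThresholds(
            min_features=self.min_features,
            max_mito=self.max_mito,
            min_cells_per_gene=self.min_cells_per_gene,
            expressed_min_count=self.expressed_min_count,
            filter_logic=self.filter_logic,
        )

    def fit(self, X: ad.AnnData, y=None):
        filtered, report, n_genes = run_qc(X.copy(), self._thresholds())
        self.cells_kept_ = filtered.obs.index.to_numpy()
        self.genes_kept_ = filtered.var.index.to_numpy()
        self.report_ = report
        self.n_genes_removed_ = n_genes
        return self

    def transform(self, X: ad.AnnData) -> ad.AnnData:
        if not hasattr(self, "cells_kept_"):
            raise RuntimeError("QCFilter is not fitted")
        cells = X.obs.index.intersection(self.cells_kept_)
        return X[cells, self.genes_kept_].copy()
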