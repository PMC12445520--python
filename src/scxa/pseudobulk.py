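"""Pseudobulk aggregation and library-size normalization.

Single-cell counts are summed within (sample, cell type) units so the
biological replicate is the male, not the cell. Units are normalized by
trimmed mean of M-values (TMM): pairwise log-ratios against a reference
unit are trimmed (30% on M, 5% on A) and combined by precision weighting;
factors are rescaled to geometric mean 1 and divide the library size when
computing CPM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["PseudobulkTable", "aggregate_pseudobulk", "tmm_norm_factors", "TMMNormalizer"]


@dataclass
class PseudobulkTable:
    """Summed counts per (sample, cell type) with normalization state."""

    counts: pd.DataFrame  # units x genes
    meta: pd.DataFrame  # unit, sample_id, cell_type, genotype, n_cells
    gene_anno: pd.DataFrame  # gene_id, chromosome, class
    norm_factors: pd.Series | None = None

    @property
    def lib_size(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def cpm(self) -> pd.DataFrame:
        """Counts per million on effective library sizes (lib_size * factor)."""
        nf = self.norm_factors if self.norm_factors is not None else 1.0
        eff = self.lib_size * nf
        return self.counts.div(eff, axis=0) * 1e6

    def normalize(self, method: str = "tmm") -> "PseudobulkTable":
        if method == "tmm":
            self.norm_factors = pd.Series(
                tmm_norm_factors(self.counts.to_numpy().T), index=self.counts.index
            )
        elif method == "total":
            self.norm_factors = pd.Series(1.0, index=self.counts.index)
        else:
            raise ValueError("method must be 'tmm' or 'total'")
        return self


def aggregate_pseudobulk(adata, sample_key: str = "sample_id", celltype_key: str = "cell_type") -> PseudobulkTable:
    """Sum counts of all cells in each (sample, cell type) unit.

    Units with zero cells are absent. Column sums are exact integer sums of
    the cell-level matrix.
    """
    for key in (sample_key, celltype_key):
        if key not in adata.obs:
            raise ValueError(f"missing cell label column {key!r}")
    obs = adata.obs
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    groups = obs.groupby([sample_key, celltype_key], observed=True).indices
    rows, meta_rows = [], []
    for (sample, ctype), idx in groups.items():
        rows.append(np.asarray(X[idx].sum(axis=0)).ravel())
        geno = obs["genotype"].iloc[idx[0]] if "genotype" in obs else "NA"
        meta_rows.append((f"{sample}|{ctype}", sample, ctype, geno, len(idx)))
    meta = pd.DataFrame(
        meta_rows, columns=["unit", "sample_id", "cell_type", "genotype", "n_cells"]
    ).set_index("unit", drop=False)
    counts = pd.DataFrame(
        np.vstack(rows).astype(np.int64), index=meta.index, columns=adata.var.index
    )
    anno_cols = [c for c in ("gene_id", "chromosome", "class") if c in adata.var]
    return PseudobulkTable(counts=counts, meta=meta, gene_anno=adata.var[anno_cols].copy())


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim=0.3, sum_trim=0.05):
    """TMM factor of one unit against the reference (both 1-D count arrays)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_norm_factors(counts, lib_size=None, logratio_trim: float = 0.3, sum_trim: float = 0.05) -> np.ndarray:
    """TMM normalization factors for a genes x units count matrix.

    The reference is the unit whose upper-quartile (of counts/library size)
    is closest to the mean upper-quartile. Factors are rescaled to geometric
    mean 1. A unit with a single expressed gene gets factor 1 with a warning.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2:
        raise ValueError("counts must be genes x units")
    n_units = y.shape[1]
    lib = np.asarray(lib_size, dtype=float) if lib_size is not None else y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be > 0")
    single = (y > 0).sum(axis=0) <= 1
    if single.any():
        warnings.warn("unit with <= 1 expressed gene; norm factor set to 1")
    f75 = np.array([np.quantile(y[:, i] / lib[i], 0.75) for i in range(n_units)])
    if np.median(f75) < 1e-20:
        ref = int(np.argmax(np.sqrt(y).sum(axis=0)))
    else:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(n_units)
    for i in range(n_units):
        if single[i]:
            continue
        factors[i] = _tmm_pair(
            y[:, i], y[:, ref], lib[i], lib[ref], logratio_trim, sum_trim
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Transformer computing TMM factors and CPM for units x genes counts."""

    def __init__(self, logratio_trim: float = 0.3, sum_trim: float = 0.05):
        self.logratio_trim = logratio_trim
        self.sum_trim = sum_trim

    def fit(self, X, y=None):
        """X: units x genes nonnegative counts (array or DataFrame)."""
        arr = X.to_numpy() if hasattr(X, "to_numpy") else np.asarray(X)
        self.lib_size_ = arr.sum(axis=1)
        self.norm_factors_ = tmm_norm_factors(
            arr.T, self.lib_size_, self.logratio_trim, self.sum_trim
        )
        return self

    def transform(self, X) -> np.ndarray:
        """CPM on effective library sizes of the fitted units."""
        arr = X.to_numpy() if hasattr(X, "to_numpy") else np.asarray(X)
        eff = self.lib_size_ * self.norm_factors_
        return arr / eff[:, None] * 1e6
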