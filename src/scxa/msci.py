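"""Per-cell X:A expression metrics and the X-inactivation classifier.

Tests for meiotic sex chromosome inactivation (MSCI): if the X were silenced
during meiosis, germline cells would show a per-cell X:A expression ratio at
or below 0.33 (half dosage would instead sit near 0.5). The ratio is
computed two ways — as a count of expressed genes (count > 1) and as the
ratio of per-cell CPM summaries — and cells at or below the threshold are
flagged as inactivated. A contingency chi-square compares the inactivated
fraction between germline and soma.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin

from .config import GERMLINE_STAGES
from .stats import contingency_chi2, fisher_exact_2x2

INACTIVATION_THRESHOLD = 0.33
EXPRESSED_MIN_COUNT = 2  # "counts > 1"


def _dense(X):
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def expressed_gene_counts(counts, chromosome) -> tuple:
    """Counts of expressed (count > 1) autosomal and X-linked genes per cell.

    ``counts`` is cells x genes (array or sparse); MT genes are excluded
    from both tallies. Returns ``(n_expr_auto, n_expr_X)`` arrays.
    """
    chromosome = np.asarray(chromosome)
    expr = _dense(counts) >= EXPRESSED_MIN_COUNT
    is_x = chromosome == "chrX"
    is_auto = (chromosome != "chrX") & (chromosome != "MT")
    return expr[:, is_auto].sum(axis=1), expr[:, is_x].sum(axis=1)


def cell_xa_cpm_ratio(counts, chromosome, summary: str = "median") -> np.ndarray:
    """Per-cell X:A CPM ratio.

    CPM is computed within the cell over non-MT counts; the ratio is
    summary(CPM of expressed X genes) / summary(CPM of expressed autosomal
    genes) with summary median (default) or mean. Cells without expressed X
    genes get 0; cells without expressed autosomal genes get NaN (excluded
    downstream).
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    chromosome = np.asarray(chromosome)
    X = _dense(counts).astype(float)
    keep = chromosome != "MT"
    X = X[:, keep]
    chrom = chromosome[keep]
    total = X.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    cpm = X * 1e6 / total
    expr = X >= EXPRESSED_MIN_COUNT
    is_x = chrom == "chrX"
    fn = np.median if summary == "median" else np.mean
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        a = cpm[i, expr[i] & ~is_x]
        x = cpm[i, expr[i] & is_x]
        if a.size == 0:
            out[i] = np.nan
        elif x.size == 0:
            out[i] = 0.0
        else:
            out[i] = fn(x) / fn(a)
    return out


def classify_inactivation(ratio, threshold: float = INACTIVATION_THRESHOLD):
    """Inactivated iff X:A ratio <= threshold (inclusive boundary)."""
    r = np.asarray(ratio, dtype=float)
    return r <= threshold


def cell_xa_stats(adata, summary: str = "median", threshold: float = INACTIVATION_THRESHOLD) -> pd.DataFrame:
    """Per-cell table: expressed-gene counts, ratios, inactivation flag."""
    chrom = adata.var["chromosome"].to_numpy()
    n_auto, n_x = expressed_gene_counts(adata.X, chrom)
    cpm_ratio = cell_xa_cpm_ratio(adata.X, chrom, summary=summary)
    with np.errstate(divide="ignore", invalid="ignore"):
        expressed_ratio = np.where(n_auto > 0, n_x / np.maximum(n_auto, 1), np.nan)
    df = pd.DataFrame(
        {
            "barcode": adata.obs.index,
            "n_expr_auto": n_auto,
            "n_expr_X": n_x,
            "expressed_ratio": expressed_ratio,
            "cpm_xa_ratio": cpm_ratio,
        }
    ).set_index("barcode", drop=False)
    inact = pd.array(
        classify_inactivation(np.nan_to_num(cpm_ratio), threshold), dtype="boolean"
    )
    inact[np.isnan(cpm_ratio)] = pd.NA
    df["inactivated"] = inact
    for col in ("cell_type", "sample_id", "genotype"):
        if col in adata.obs:
            df[col] = adata.obs[col].to_numpy()
    return df


def inactivation_contingency_test(stats_df: pd.DataFrame, germline_types=GERMLINE_STAGES, method: str = "chi2"):
    """Compare inactivated fractions between germline and somatic compartments.

    Returns ``(chi2, df, p, table)`` where table rows are (germline, soma)
    and columns (inactivated, active). ``method='fisher'`` substitutes
    Fisher's exact test (p only, chi2 reported as NaN).
    """
    d = stats_df.dropna(subset=["inactivated"])
    if "cell_type" not in d:
        raise ValueError("cell_type column required")
    is_germ = d["cell_type"].isin(germline_types)
    if is_germ.all() or not is_germ.any():
        raise ValueError("both compartments must be non-empty")
    flags = d["inactivated"].astype(bool)
    table = np.array(
        [
            [int((flags & is_germ).sum()), int((~flags & is_germ).sum())],
            [int((flags & ~is_germ).sum()), int((~flags & ~is_germ).sum())],
        ]
    )
    if method == "fisher":
        return float("nan"), 1, fisher_exact_2x2(table), table
    chi2, df, p = contingency_chi2(table)
    return chi2, df, p, table


class XInactivationClassifier(BaseEstimator, ClassifierMixin):
    """Classify cells as X-inactivated from their X:A CPM ratio.

    Parameters
    ----------
    threshold : float
        Inactivation boundary on the per-cell X:A CPM ratio (inclusive).
    summary : str
        Per-cell CPM summary over expressed genes, 'median' or 'mean'.
    """

    def __init__(self, threshold: float = INACTIVATION_THRESHOLD, summary: str = "median"):
        self.threshold = threshold
        self.summary = summary

    def fit(self, X, y=None):
        """X is an AnnData with chromosome annotation; computes per-cell stats."""
        self.stats_ = cell_xa_stats(X, summary=self.summary, threshold=self.threshold)
        self.threshold_ = self.threshold
        return self

    def predict(self, X) -> np.ndarray:
        """Boolean inactivation flags for the cells of AnnData ``X``."""
        ratio = cell_xa_cpm_ratio(X.X, X.var["chromosome"].to_numpy(), summary=self.summary)
        out = classify_inactivation(ratio, self.threshold)
        out[np.isnan(ratio)] = False
        return out
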