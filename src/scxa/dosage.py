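"""Dosage-compensation statistic: per-unit log2(X:A) with filters and tests.

For each (sample, cell type) pseudobulk unit the statistic is, per X-linked
gene, log2(CPM of the gene / median CPM of filtered autosomal genes of the
same unit). A value of 0 means even X and autosomal expression (complete
compensation); -1 means the X at half the autosomal level (no compensation
in a male). Per cell type and genotype, genes are summarized across samples
and tested against 0 with a two-sided Wilcoxon signed-rank (mu = 0);
genotypes are compared by rank-sum over the per-gene values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .pseudobulk import PseudobulkTable
from .stats import mann_whitney, wilcoxon_signed_rank

MIN_CELL_FRACTION = 0.05
MIN_LOG2_CPM = 2.0


def dosage_gene_filter(
    adata,
    pb: PseudobulkTable,
    cell_type: str,
    min_cell_fraction: float = MIN_CELL_FRACTION,
    min_log2_cpm: float = MIN_LOG2_CPM,
    expressed_min_count: int = 2,
) -> pd.Index:
    """Genes eligible for the dosage statistic in one cell type.

    Kept iff expressed (count > 1) in at least ``min_cell_fraction`` of the
    cell type's cells AND log2(CPM) > ``min_log2_cpm`` in strictly more than
    half of the ST samples or strictly more than half of the SR samples.
    """
    cells = adata.obs["cell_type"] == cell_type
    if not cells.any():
        raise ValueError(f"no cells of type {cell_type!r}")
    X = adata.X[cells.to_numpy()]
    if sparse.issparse(X):
        frac = np.asarray((X >= expressed_min_count).sum(axis=0)).ravel() / X.shape[0]
    else:
        frac = (np.asarray(X) >= expressed_min_count).sum(axis=0) / X.shape[0]
    pass_cells = frac >= min_cell_fraction

    units = pb.meta[pb.meta["cell_type"] == cell_type]
    cpm = pb.cpm().loc[units.index]
    with np.errstate(divide="ignore"):
        log2cpm = np.log2(cpm.to_numpy())
    over = log2cpm > min_log2_cpm
    pass_pb = np.zeros(cpm.shape[1], dtype=bool)
    for geno in ("ST", "SR"):
        rows = (units["genotype"] == geno).to_numpy()
        if rows.sum() == 0:
            continue
        pass_pb |= over[rows].sum(axis=0) > rows.sum() / 2
    keep = pass_cells & pass_pb
    return adata.var.index[keep]


def gene_log2_xa(cpm_row: pd.Series, genes: pd.Index, auto_genes: pd.Index) -> pd.Series:
    """Per-gene log2(CPM / median autosomal CPM) within one unit.

    Genes with zero CPM are excluded (logged via a warning); the autosomal
    median is over the unit's filtered autosomal genes.
    """
    med = float(np.median(cpm_row[auto_genes]))
    if med <= 0:
        raise ValueError("autosomal median CPM is zero")
    vals = cpm_row[genes]
    zero = vals <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} X-linked genes with zero CPM excluded")
        vals = vals[~zero]
    return np.log2(vals / med)


def dosage_test(values, mu: float = 0.0) -> float:
    """Two-sided Wilcoxon signed-rank p for deviation of log2(X:A) from mu."""
    return wilcoxon_signed_rank(values, mu=mu)


def dosage_compare(st_values, sr_values) -> float:
    """Two-sided rank-sum p comparing per-gene log2(X:A) between genotypes."""
    return mann_whitney(st_values, sr_values)


@dataclass
class DosageResult:
    """Per-cell-type, per-genotype dosage summary."""

    cell_type: str
    genotype: str
    genes: pd.Series  # per-gene mean log2(X:A) across the genotype's samples
    median_log2_xa: float
    wilcoxon_p_vs_zero: float
    n_genes: int
    comparison_p: float | None = None
    gene_class: str = "all"


def _per_gene_values(pb, cpm, cell_type, genotype, x_genes, auto_genes):
    units = pb.meta[
        (pb.meta["cell_type"] == cell_type) & (pb.meta["genotype"] == genotype)
    ]
    if len(units) == 0:
        return None
    per_unit = []
    for u in units.index:
        per_unit.append(gene_log2_xa(cpm.loc[u], x_genes, auto_genes))
    mat = pd.concat(per_unit, axis=1)
    return mat.mean(axis=1).dropna()


def dosage_analysis(
    adata,
    pb: PseudobulkTable,
    cell_types=None,
    genotypes=("ST", "SR"),
    min_cell_fraction: float = MIN_CELL_FRACTION,
    min_log2_cpm: float = MIN_LOG2_CPM,
    by_class: bool = False,
) -> list[DosageResult]:
    """Full dosage-compensation analysis across cell types and genotypes.

    Per cell type: apply the two gene filters, compute each X gene's mean
    log2(X:A) across the genotype's samples, the median over genes, the
    Wilcoxon p against 0, and the ST-vs-SR rank-sum comparison. With
    ``by_class`` the per-class results (testis-specific vs broad) are
    appended.
    """
    if pb.norm_factors is None:
        pb.normalize("tmm")
    cpm = pb.cpm()
    chrom = pb.gene_anno["chromosome"]
    if cell_types is None:
        cell_types = list(pb.meta["cell_type"].unique())
    results: list[DosageResult] = []
    for ctype in cell_types:
        eligible = dosage_gene_filter(
            adata, pb, ctype, min_cell_fraction, min_log2_cpm
        )
        x_genes = eligible[chrom.loc[eligible] == "chrX"]
        auto_genes = eligible[chrom.loc[eligible].isin(("chr1", "chr2"))]
        if len(x_genes) == 0 or len(auto_genes) == 0:
            warnings.warn(f"{ctype}: no filtered X or autosomal genes; skipped")
            continue
        per_geno = {}
        for geno in genotypes:
            vals = _per_gene_values(pb, cpm, ctype, geno, x_genes, auto_genes)
            if vals is None or len(vals) == 0:
                continue
            per_geno[geno] = vals
        comparison_p = (
            dosage_compare(per_geno["ST"], per_geno["SR"])
            if {"ST", "SR"} <= set(per_geno)
            else None
        )
        class_of = (
            pb.gene_anno["class"] if "class" in pb.gene_anno else None
        )
        for geno, vals in per_geno.items():
            results.append(
                DosageResult(
                    cell_type=ctype,
                    genotype=geno,
                    genes=vals,
                    median_log2_xa=float(np.median(vals)),
                    wilcoxon_p_vs_zero=dosage_test(vals),
                    n_genes=len(vals),
                    comparison_p=comparison_p,
                )
            )
            if by_class and class_of is not None:
                results.extend(stratify_by_class(results[-1], class_of))
    return results


def stratify_by_class(result: DosageResult, gene_class: pd.Series) -> list[DosageResult]:
    """Recompute a dosage result within each gene class (e.g. testis-specific)."""
    out = []
    classes = gene_class.loc[result.genes.index]
    for cls in classes.unique():
        vals = result.genes[classes == cls]
        if len(vals) == 0:
            warnings.warn(f"empty gene class {cls!r}; omitted")
            continue
        out.append(
            DosageResult(
                cell_type=result.cell_type,
                genotype=result.genotype,
                genes=vals,
                median_log2_xa=float(np.median(vals)),
                wilcoxon_p_vs_zero=dosage_test(vals),
                n_genes=len(vals),
                gene_class=str(cls),
            )
        )
    return out


def dosage_summary(results: list[DosageResult]) -> pd.DataFrame:
    rows = [
        {
            "cell_type": r.cell_type,
            "genotype": r.genotype,
            "gene_class": r.gene_class,
            "median_log2_xa": r.median_log2_xa,
            "p_vs_zero": r.wilcoxon_p_vs_zero,
            "p_ST_vs_SR": r.comparison_p,
            "n_genes": r.n_genes,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
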