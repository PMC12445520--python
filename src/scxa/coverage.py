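"""DNA coverage differences between genotypes and their link to expression.

Per-gene read-depth differences between ST and SR individuals proxy copy
number variation; they are tested with the same NB conditional exact test
as expression (library normalization by total counts by default, since
genome-wide coverage is less composition-biased than expression). The
association between expression and coverage log2 fold changes is a
Spearman rank correlation, over all genes and over the genes significant
in both analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import estimate_dispersions, nb_exact_test
from .pseudobulk import tmm_norm_factors
from .simulate import CoverageTable
from .stats import bh_adjust, spearman_association


@dataclass
class AssociationResult:
    rho: float
    p: float
    n_genes: int
    subset: str  # all | significant-both


def coverage_exact_test(
    table: CoverageTable,
    normalization: str = "total",
    prior_n: float = 10.0,
) -> pd.DataFrame:
    """Per-gene (log2fc SR vs ST, p, fdr) from the NB exact test."""
    counts = table.counts.to_numpy()
    libs = counts.sum(axis=1).astype(float)
    if normalization == "tmm":
        libs = libs * tmm_norm_factors(counts.T, libs)
    elif normalization != "total":
        raise ValueError("normalization must be 'total' or 'tmm'")
    groups = table.genotype.to_numpy()
    disp = estimate_dispersions(counts, libs, groups, prior_n=prior_n)
    log2fc, p = nb_exact_test(
        counts, libs, groups, disp.tagwise_phi, group_order=("SR", "ST")
    )
    return pd.DataFrame(
        {
            "gene": table.counts.columns,
            "log2fc": log2fc,
            "p": p,
            "fdr": bh_adjust(p),
        }
    ).set_index("gene", drop=False)


def expression_coverage_association(
    expr_log2fc: pd.Series,
    cov_log2fc: pd.Series,
    subset: str = "all",
    absolute: bool = False,
) -> AssociationResult:
    """Spearman association between expression and coverage fold changes.

    Vectors are aligned on their (gene) index; ``absolute=True`` correlates
    magnitudes instead of signed values.
    """
    genes = expr_log2fc.index.intersection(cov_log2fc.index)
    x = expr_log2fc.loc[genes].to_numpy(dtype=float)
    y = cov_log2fc.loc[genes].to_numpy(dtype=float)
    if absolute:
        x, y = np.abs(x), np.abs(y)
    rho, p = spearman_association(x, y)
    return AssociationResult(rho=rho, p=p, n_genes=len(genes), subset=subset)


def joint_candidates(
    de_results: pd.DataFrame,
    cov_results: pd.DataFrame,
    p_cut: float = 0.05,
    use_column: str = "p",
) -> pd.DataFrame:
    """Genes significant (p < p_cut) in both expression and coverage.

    Returns a table with both log2 fold changes, ordered by expression p.
    """
    de_sig = de_results[de_results[use_column] < p_cut]
    cov_sig = cov_results[cov_results[use_column] < p_cut]
    genes = de_sig.index.intersection(cov_sig.index)
    out = pd.DataFrame(
        {
            "gene": genes,
            "expr_log2fc": de_sig.loc[genes, "log2fc"],
            "expr_p": de_sig.loc[genes, use_column],
            "cov_log2fc": cov_sig.loc[genes, "log2fc"],
            "cov_p": cov_sig.loc[genes, use_column],
        }
    ).set_index("gene", drop=False)
    return out.sort_values("expr_p")
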