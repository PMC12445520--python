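"""Pseudobulk negative-binomial differential expression (SR vs ST).

One engine serves both expression and DNA-coverage contrasts: counts are
mapped to a common library size by quantile-to-quantile NB pseudo-counts,
a common dispersion is estimated by conditional maximum likelihood and
shrunk gene-wise by weighted likelihood, and the two-sided conditional
exact test is applied to each gene's group-total split. Conditional on the
total s and equal library sizes, the split of group 1 is exactly
BetaBinomial(s, n1/phi, n2/phi) — binomial in the Poisson limit — which is
what the implementation evaluates. Significance uses |log2FC| > 1 and
BH-FDR < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, gammaln
from sklearn.base import BaseEstimator

from .stats import bh_adjust

__all__ = [
    "DispersionEstimate",
    "estimate_dispersions",
    "nb_exact_test",
    "de_per_celltype",
    "PseudobulkDE",
]

LOG2FC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05
#: totals above this use the moment-matched normal tail of the beta-binomial
EXACT_TOTAL_CAP = 4000
#: dispersion values below this are treated as Poisson
POISSON_EPS = 1e-8

_PHI_GRID = np.concatenate([[1e-4], np.geomspace(3e-4, 5.0, 79)])


@dataclass
class DispersionEstimate:
    common_phi: float
    tagwise_phi: np.ndarray
    prior_n: float


def q2qnbinom(x, input_mean, output_mean, dispersion: float = 0.0):
    """Quantile-to-quantile NB mapping of counts to a new mean.

    Averages the normal- and gamma-approximation quantile maps, preserving
    each observation's tail probability while moving it from ``input_mean``
    to ``output_mean`` (the library-equalization device of exact-test DE).
    """
    x = np.asarray(x, dtype=float)
    mi = np.broadcast_to(np.asarray(input_mean, dtype=float), x.shape).copy()
    mo = np.broadcast_to(np.asarray(output_mean, dtype=float), x.shape).copy()
    eps = 1e-14
    zero = (mi < eps) | (mo < eps)
    mi[zero] += 0.25
    mo[zero] += 0.25
    ri = 1 + dispersion * mi
    ro = 1 + dispersion * mo
    vi = mi * ri
    vo = mo * ro
    out = np.empty_like(x)
    upper = x >= mi
    for mask, tail in ((upper, False), (~upper, True)):
        if not mask.any():
            continue
        p_norm = stats.norm.cdf(x[mask], loc=mi[mask], scale=np.sqrt(vi[mask])) if tail else stats.norm.sf(
            x[mask], loc=mi[mask], scale=np.sqrt(vi[mask])
        )
        p_gam = stats.gamma.cdf(x[mask], a=mi[mask] / ri[mask], scale=ri[mask]) if tail else stats.gamma.sf(
            x[mask], a=mi[mask] / ri[mask], scale=ri[mask]
        )
        # tail probabilities can underflow to exactly 0 for extreme outliers
        p_norm = np.clip(p_norm, 1e-300, 1.0)
        p_gam = np.clip(p_gam, 1e-300, 1.0)
        q_norm = (
            stats.norm.ppf(p_norm, loc=mo[mask], scale=np.sqrt(vo[mask]))
            if tail
            else stats.norm.isf(p_norm, loc=mo[mask], scale=np.sqrt(vo[mask]))
        )
        q_gam = (
            stats.gamma.ppf(p_gam, a=mo[mask] / ro[mask], scale=ro[mask])
            if tail
            else stats.gamma.isf(p_gam, a=mo[mask] / ro[mask], scale=ro[mask])
        )
        out[mask] = (q_norm + q_gam) / 2
    bad = ~np.isfinite(out)
    if bad.any():  # fall back to plain mean scaling
        out[bad] = x[bad] * mo[bad] / mi[bad]
    return np.maximum(out, 0.0)


def _one_group_mu(counts, lib_sizes, dispersion: float) -> np.ndarray:
    """Per-gene NB MLE of the common abundance mu (mean_i = mu * N_i)."""
    y = np.asarray(counts, dtype=float)  # units x genes
    N = np.asarray(lib_sizes, dtype=float)[:, None]
    mu = y.sum(axis=0) / N.sum()
    for _ in range(12):  # Fisher scoring with log link
        m = np.maximum(mu[None, :] * N, 1e-12)
        denom = 1 + dispersion * m
        num = (y / denom).sum(axis=0)
        den = (m / denom).sum(axis=0)
        mu = np.where(den > 0, mu * num / np.maximum(den, 1e-300), 0.0)
    return mu


def equalize_lib_sizes(counts, lib_sizes, dispersion: float = 0.0):
    """Map counts to pseudo-counts at the geometric-mean library size."""
    y = np.asarray(counts, dtype=float)
    N = np.asarray(lib_sizes, dtype=float)
    common = float(np.exp(np.mean(np.log(N))))
    mu = _one_group_mu(y, N, dispersion)
    pseudo = q2qnbinom(y, mu[None, :] * N[:, None], mu[None, :] * common, dispersion)
    return pseudo, common


def _cond_loglik(pseudo, groups, phi: float) -> np.ndarray:
    """Per-gene NB conditional log-likelihood given group totals (equal libs)."""
    r = 1.0 / max(phi, 1e-10)
    ll = np.zeros(pseudo.shape[1])
    for g in np.unique(groups):
        yg = pseudo[groups == g]
        n = yg.shape[0]
        z = yg.sum(axis=0)
        ll += (
            gammaln(yg + r).sum(axis=0)
            - n * gammaln(r)
            + gammaln(n * r)
            - gammaln(z + n * r)
        )
    return ll


def estimate_dispersions(counts, lib_sizes, groups, prior_n: float = 10.0) -> DispersionEstimate:
    """Common + tagwise NB dispersions (var = mu + phi mu^2).

    Common phi maximizes the summed conditional likelihood on
    library-equalized pseudo-counts over a dispersion grid; tagwise phi
    maximizes each gene's conditional likelihood plus ``prior_n`` times the
    average likelihood (weighted-likelihood shrinkage toward common).
    Underdispersed genes are floored at 0.
    """
    groups = np.asarray(groups)
    for g in np.unique(groups):
        if (groups == g).sum() < 2:
            raise ValueError("need >= 2 units per group")
    y = np.asarray(counts, dtype=float)
    pseudo0, _ = equalize_lib_sizes(y, lib_sizes, 0.0)
    ll = np.stack([_cond_loglik(pseudo0, groups, p) for p in _PHI_GRID], axis=1)
    total = ll.sum(axis=0)
    k = int(np.argmax(total))
    common = 0.0 if k == 0 else float(_PHI_GRID[k])
    # re-equalize at the common dispersion and refine
    pseudo, _ = equalize_lib_sizes(y, lib_sizes, common)
    ll = np.stack([_cond_loglik(pseudo, groups, p) for p in _PHI_GRID], axis=1)
    total = ll.sum(axis=0)
    k = int(np.argmax(total))
    common = 0.0 if k == 0 else float(_PHI_GRID[k])
    weighted = ll + prior_n * (ll.mean(axis=0)[None, :])
    kk = np.argmax(weighted, axis=1)
    tagwise = np.where(kk == 0, 0.0, _PHI_GRID[kk])
    if counts.shape[1] == 1:
        tagwise = np.array([common])
    return DispersionEstimate(common_phi=common, tagwise_phi=tagwise, prior_n=prior_n)


def _split_two_sided_p(s1, s, r1, r2):
    """Two-sided p for the observed split s1 of total s under BetaBinom(s, r1, r2).

    Doubles the smaller tail, capped at 1. Scalar inputs."""
    if s == 0:
        return 1.0
    if s <= EXACT_TOTAL_CAP:
        x = np.arange(s + 1)
        logpmf = (
            gammaln(s + 1)
            - gammaln(x + 1)
            - gammaln(s - x + 1)
            + betaln(x + r1, s - x + r2)
            - betaln(r1, r2)
        )
        pmf = np.exp(logpmf - logpmf.max())
        pmf /= pmf.sum()
        p_low = pmf[: s1 + 1].sum()
        p_high = pmf[s1:].sum()
    else:
        ab = r1 + r2
        m = s * r1 / ab
        sd = np.sqrt(s * r1 * r2 * (ab + s) / (ab**2 * (ab + 1)))
        p_low = stats.norm.cdf(s1 + 0.5, loc=m, scale=sd)
        p_high = stats.norm.sf(s1 - 0.5, loc=m, scale=sd)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def nb_exact_test(
    counts,
    lib_sizes,
    groups,
    phi,
    group_order=None,
    prior_count: float = 0.5,
):
    """Conditional NB exact test per gene between two groups.

    ``counts`` is units x genes; ``groups`` labels each unit; ``phi`` is a
    scalar or per-gene dispersion. Counts are first equalized to a common
    library size. Returns ``(log2fc, p)`` with log2fc of
    ``group_order[0]`` over ``group_order[1]`` (defaults to sorted labels)
    from prior-offset group mean pseudo-counts.
    """
    groups = np.asarray(groups)
    labels = list(group_order) if group_order is not None else sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    y = np.asarray(counts, dtype=float)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[1],))
    pseudo, _ = equalize_lib_sizes(y, lib_sizes, float(np.median(phi_arr)))
    in1 = groups == labels[0]
    in2 = groups == labels[1]
    n1, n2 = int(in1.sum()), int(in2.sum())
    s1 = np.round(pseudo[in1].sum(axis=0)).astype(np.int64)
    s2 = np.round(pseudo[in2].sum(axis=0)).astype(np.int64)
    s = s1 + s2
    pvals = np.ones(y.shape[1])
    frac1 = n1 / (n1 + n2)
    for j in range(y.shape[1]):
        if s[j] == 0:
            continue
        if phi_arr[j] < POISSON_EPS:
            p_low = stats.binom.cdf(s1[j], s[j], frac1)
            p_high = stats.binom.sf(s1[j] - 1, s[j], frac1)
            pvals[j] = min(1.0, 2.0 * min(p_low, p_high))
        else:
            pvals[j] = _split_two_sided_p(
                int(s1[j]), int(s[j]), n1 / phi_arr[j], n2 / phi_arr[j]
            )
    log2fc = np.log2((s1 / n1 + prior_count) / (s2 / n2 + prior_count))
    log2fc = np.where(s == 0, 0.0, log2fc)
    return log2fc, pvals


def de_per_celltype(
    adata,
    pb,
    cell_type: str,
    prior_n: float = 10.0,
    lfc_threshold: float = LOG2FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    gene_filter=None,
) -> pd.DataFrame | None:
    """SR-vs-ST differential expression for one cell type.

    Genes are pre-filtered with the dosage filters (or an explicit
    ``gene_filter`` index); FDR is computed within the cell type. Returns a
    per-gene table or None (with a warning) when either genotype has fewer
    than two pseudobulk units.
    """
    from .dosage import dosage_gene_filter

    units = pb.meta[pb.meta["cell_type"] == cell_type]
    n_st = int((units["genotype"] == "ST").sum())
    n_sr = int((units["genotype"] == "SR").sum())
    if n_st < 2 or n_sr < 2:
        warnings.warn(f"{cell_type}: <2 replicates per genotype; skipped")
        return None
    genes = (
        gene_filter
        if gene_filter is not None
        else dosage_gene_filter(adata, pb, cell_type)
    )
    if len(genes) == 0:
        warnings.warn(f"{cell_type}: no genes pass filters; skipped")
        return None
    counts = pb.counts.loc[units.index, genes].to_numpy()
    libs = pb.counts.loc[units.index].sum(axis=1).to_numpy()
    groups = units["genotype"].to_numpy()
    disp = estimate_dispersions(counts, libs, groups, prior_n=prior_n)
    log2fc, p = nb_exact_test(
        counts, libs, groups, disp.tagwise_phi, group_order=("SR", "ST")
    )
    fdr = bh_adjust(p)
    significant = (fdr < fdr_threshold) & (np.abs(log2fc) > lfc_threshold)
    direction = np.where(
        ~significant, "unbiased", np.where(log2fc > 0, "SR-biased", "ST-biased")
    )
    chrom = (
        pb.gene_anno.loc[genes, "chromosome"].to_numpy()
        if "chromosome" in pb.gene_anno
        else np.repeat("NA", len(genes))
    )
    return pd.DataFrame(
        {
            "gene": genes,
            "cell_type": cell_type,
            "chromosome": chrom,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "significant": significant,
            "direction": direction,
        }
    ).set_index("gene", drop=False)


class PseudobulkDE(BaseEstimator):
    """Estimator form of the NB exact-test DE engine.

    ``fit(X, y)`` takes units x genes counts and binary group labels;
    fitted attributes hold dispersions and the per-gene results table.
    """

    def __init__(
        self,
        prior_n: float = 10.0,
        lfc_threshold: float = LOG2FC_THRESHOLD,
        fdr_threshold: float = FDR_THRESHOLD,
        prior_count: float = 0.5,
        group_order=None,
    ):
        self.prior_n = prior_n
        self.lfc_threshold = lfc_threshold
        self.fdr_threshold = fdr_threshold
        self.prior_count = prior_count
        self.group_order = group_order

    def fit(self, X, y):
        counts = X.to_numpy() if hasattr(X, "to_numpy") else np.asarray(X)
        genes = (
            list(X.columns) if hasattr(X, "columns") else list(range(counts.shape[1]))
        )
        libs = counts.sum(axis=1)
        disp = estimate_dispersions(counts, libs, y, prior_n=self.prior_n)
        log2fc, p = nb_exact_test(
            counts,
            libs,
            y,
            disp.tagwise_phi,
            group_order=self.group_order,
            prior_count=self.prior_count,
        )
        fdr = bh_adjust(p)
        self.dispersion_ = disp
        self.results_ = pd.DataFrame(
            {
                "gene": genes,
                "log2fc": log2fc,
                "p": p,
                "fdr": fdr,
                "significant": (fdr < self.fdr_threshold)
                & (np.abs(log2fc) > self.lfc_threshold),
            }
        ).set_index("gene", drop=False)
        return self
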