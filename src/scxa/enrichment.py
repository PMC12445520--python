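"""Chromosomal enrichment of DE genes and the pseudo-replicate null.

Enrichment: per-gene significance flags are regressed on chromosome class
and cell type with a binomial GLM (Significant ~ chromosome * cell_type);
nested models are compared by likelihood-ratio chi-square (interaction
first, then the chromosome main effect).

Pseudo-replicate null: to calibrate the percent of DE genes expected with
no true genotype difference, pseudo-samples of cells are drawn with
replacement from one genotype's pool (ST vs ST) and compared to the
genotype contrast (ST vs SR) with the same DE engine and thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats

from .de import estimate_dispersions, nb_exact_test
from .stats import bh_adjust


@dataclass
class EnrichmentFit:
    coefficients: pd.Series
    lrt: pd.DataFrame  # comparison, chi2, df, p
    separation: bool
    model: object


def _fit_glm(y, X):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    return res


def fit_enrichment_glm(significant, chromosome, cell_type) -> EnrichmentFit:
    """Binomial GLM of DE status on chromosome class x cell type.

    ``chromosome`` may be raw chromosome names; anything named 'chrX'/'X' is
    the X class, the rest autosomal. Returns coefficients (log-odds) and
    LRT rows for the interaction and the chromosome main effect.
    """
    sig = np.asarray(significant, dtype=float)
    chrom = np.asarray(chromosome)
    xclass = np.where(np.isin(chrom, ("chrX", "X")), "X", "autosome")
    ct = pd.Categorical(cell_type)
    df = pd.DataFrame({"sig": sig, "chrom": xclass, "cell_type": ct})
    if df["chrom"].nunique() < 2:
        raise ValueError("need both chromosome classes")

    X_full = pd.get_dummies(df[["cell_type"]], drop_first=True, dtype=float)
    X_full.insert(0, "chrom_X", (df["chrom"] == "X").astype(float))
    inter = pd.DataFrame(index=df.index)
    chrom_cols = ["chrom_X"]
    ct_cols = [c for c in X_full if c.startswith("cell_type_")]
    for cc in chrom_cols:
        for tc in ct_cols:
            inter[f"{cc}:{tc}"] = X_full[cc] * X_full[tc]
    X_inter = pd.concat([X_full, inter], axis=1)

    def with_const(x):
        return sm.add_constant(x, has_constant="add")

    fit_full = _fit_glm(sig, with_const(X_inter))
    fit_main = _fit_glm(sig, with_const(X_full))
    fit_noch = _fit_glm(sig, with_const(X_full[ct_cols]))

    rows = []
    for name, bigger, smaller in (
        ("interaction", fit_full, fit_main),
        ("chromosome", fit_main, fit_noch),
    ):
        chi2 = max(0.0, smaller.deviance - bigger.deviance)
        dof = int(bigger.df_model - smaller.df_model)
        p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
        rows.append({"comparison": name, "chi2": chi2, "df": dof, "p": p})

    mu = fit_full.fittedvalues
    separation = bool(np.any(mu < 1e-8) or np.any(mu > 1 - 1e-8) or np.any(np.abs(fit_full.params) > 15))
    if separation:
        warnings.warn("possible separation in enrichment GLM; coefficients unstable")
    return EnrichmentFit(
        coefficients=fit_full.params,
        lrt=pd.DataFrame(rows),
        separation=separation,
        model=fit_full,
    )


@dataclass
class ResamplingNull:
    """Per-repeat percent-DE distributions and their rank-sum comparison."""

    percents: pd.DataFrame  # repeat, comparison, chrom_class, percent
    comparison_p: pd.Series  # per chrom_class
    repeats: int
    seed: int


def _percent_de(
    pool_a,
    pool_b,
    rng,
    n_pseudo,
    cells_per,
    chrom_class,
    min_cell_fraction,
    min_log2_cpm,
    lfc_threshold,
    fdr_threshold,
    prior_n,
):
    """One repeat: draw pseudo-samples, run the DE engine, return percents."""
    units = []
    n_sampled = 0
    expr_cells = None
    for pool in (pool_a, pool_b):
        for _ in range(n_pseudo):
            idx = rng.integers(0, pool.shape[0], size=cells_per)
            sampled = pool[idx]
            units.append(np.asarray(sampled.sum(axis=0)).ravel())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                e = np.asarray((sampled >= 2).sum(axis=0)).ravel()
            expr_cells = e if expr_cells is None else expr_cells + e
            n_sampled += cells_per
    counts = np.vstack(units).astype(float)
    groups = np.array(["A"] * n_pseudo + ["B"] * n_pseudo)
    libs = counts.sum(axis=1)
    # both dosage-style filters within the repeat: expressed (>1) in >= 5% of
    # the sampled cells, and log2CPM > threshold in > half of either group
    cpm = counts / libs[:, None] * 1e6
    with np.errstate(divide="ignore"):
        over = np.log2(cpm) > min_log2_cpm
    keep = np.zeros(counts.shape[1], dtype=bool)
    for g in ("A", "B"):
        rows = groups == g
        keep |= over[rows].sum(axis=0) > rows.sum() / 2
    keep &= expr_cells >= min_cell_fraction * n_sampled
    if not keep.any():
        return {}
    sub = counts[:, keep]
    disp = estimate_dispersions(sub, libs, groups, prior_n=prior_n)
    log2fc, p = nb_exact_test(sub, libs, groups, disp.tagwise_phi, group_order=("B", "A"))
    fdr = bh_adjust(p)
    sig = (fdr < fdr_threshold) & (np.abs(log2fc) > lfc_threshold)
    cls = chrom_class[keep]
    out = {}
    for c in ("X", "autosome"):
        mask = cls == c
        out[c] = 100.0 * sig[mask].mean() if mask.any() else np.nan
    return out


def pseudo_replicate_null(
    adata,
    n_pseudo: int = 4,
    cells_per: int = 100,
    repeats: int = 1000,
    seed: int = 0,
    min_cell_fraction: float = 0.05,
    min_log2_cpm: float = 2.0,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    prior_n: float = 10.0,
) -> ResamplingNull:
    """Bootstrap pseudo-samples to calibrate percent-DE under the null.

    Per repeat, ``n_pseudo`` + ``n_pseudo`` pseudo-samples of ``cells_per``
    cells are drawn with replacement — both from the ST pool (ST vs ST), and
    from the ST and SR pools respectively (ST vs SR) — aggregated to
    pseudobulk, and run through the DE engine. The percent of eligible genes
    called significant is recorded per chromosome class, and the two
    percent distributions are compared by two-sided rank-sum.
    """
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    geno = adata.obs["genotype"].to_numpy()
    pools = {g: X[geno == g] for g in ("ST", "SR")}
    for g, pool in pools.items():
        if pool.shape[0] < cells_per:
            raise ValueError(f"{g} pool smaller than cells_per={cells_per}")
    chrom = adata.var["chromosome"].to_numpy()
    chrom_class = np.where(chrom == "chrX", "X", "autosome")
    chrom_class[chrom == "MT"] = "MT"

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E9]))
    rows = []
    kwargs = dict(
        n_pseudo=n_pseudo,
        cells_per=cells_per,
        chrom_class=chrom_class,
        min_cell_fraction=min_cell_fraction,
        min_log2_cpm=min_log2_cpm,
        lfc_threshold=lfc_threshold,
        fdr_threshold=fdr_threshold,
        prior_n=prior_n,
    )
    for rep in range(repeats):
        for comp, (a, b) in (
            ("ST_vs_ST", ("ST", "ST")),
            ("ST_vs_SR", ("ST", "SR")),
        ):
            pct = _percent_de(pools[a], pools[b], rng, **kwargs)
            for cls, val in pct.items():
                rows.append(
                    {"repeat": rep, "comparison": comp, "chrom_class": cls, "percent": val}
                )
    percents = pd.DataFrame(rows)
    pvals = {}
    for cls in ("X", "autosome"):
        null = percents.query("comparison == 'ST_vs_ST' and chrom_class == @cls")["percent"].dropna()
        alt = percents.query("comparison == 'ST_vs_SR' and chrom_class == @cls")["percent"].dropna()
        if len(null) and len(alt):
            if null.nunique() == 1 and alt.nunique() == 1 and null.iloc[0] == alt.iloc[0]:
                pvals[cls] = 1.0
            else:
                pvals[cls] = float(
                    stats.mannwhitneyu(null, alt, alternative="two-sided").pvalue
                )
        else:
            pvals[cls] = np.nan
    return ResamplingNull(
        percents=percents,
        comparison_p=pd.Series(pvals, name="p"),
        repeats=repeats,
        seed=seed,
    )
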