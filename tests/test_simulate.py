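"""Generator contracts: determinism, programmed means, truth round-trips."""

import numpy as np
import pandas as pd
import pytest

from scxa.config import DEFAULT_CELL_TYPES, SimulationConfig
from scxa.simulate import simulate_counts, simulate_coverage, simulate_sites


def _flat_dosage(value):
    return {t: value for t in DEFAULT_CELL_TYPES}


def _cfg(**kw):
    base = dict(
        seed=5,
        cells_per_sample_per_type={t: 20 for t in DEFAULT_CELL_TYPES},
        genes_per_chrom={"chr1": 300, "chr2": 300, "chrX": 200, "MT": 8},
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_same_seed_identical_matrices():
    a1, _ = simulate_counts(_cfg())
    a2, _ = simulate_counts(_cfg())
    assert (a1.X != a2.X).nnz == 0
    assert a1.obs.equals(a2.obs)
    a3, _ = simulate_counts(_cfg(seed=6))
    assert (a1.X != a3.X).nnz > 0


def test_counts_nonnegative_integers_and_libsizes():
    adata, _ = simulate_counts(_cfg())
    X = adata.X
    assert X.min() >= 0
    assert np.all(X.data == np.round(X.data))
    # per-cell sums are the realized library sizes by construction
    lib = np.asarray(X.sum(axis=1)).ravel()
    assert lib.sum() == X.sum()


def test_neutral_config_xa_ratio_near_one():
    """With all dosage 1 and no DE genes, X and autosomes share one rate law.

    Gene rates are narrowed (sdlog 0.1) so the Monte-Carlo error of the
    mean-count ratio reflects counting noise, not rate sampling.
    """
    cfg = _cfg(x_dosage=_flat_dosage(1.0), n_de_genes=0, baseline_logsd=0.1,
               inclusion_prob={t: 1.0 for t in DEFAULT_CELL_TYPES})
    adata, _ = simulate_counts(cfg)
    X = np.asarray(adata.X.todense(), dtype=float)
    chrom = adata.var["chromosome"].to_numpy()
    mean_x = X[:, chrom == "chrX"].mean()
    mean_a = X[:, (chrom == "chr1") | (chrom == "chr2")].mean()
    assert mean_x / mean_a == pytest.approx(1.0, abs=0.12)


def test_programmed_half_dosage_recovered_in_mean_counts():
    """Monte-Carlo: mean X count / mean autosomal count tracks d = 0.5.

    Gene rates are shared between chromosomes only in distribution, so a
    narrow rate law (sdlog 0.1) keeps the comparison against the programmed
    NB means free of rate-sampling noise.
    """
    half = _flat_dosage(0.5)
    cfg = _cfg(
        x_dosage=half,
        inclusion_prob={t: 1.0 for t in DEFAULT_CELL_TYPES},
        cells_per_sample_per_type={t: 160 for t in DEFAULT_CELL_TYPES},
        n_samples_ST=4,
        n_samples_SR=0,
        baseline_logsd=0.1,
    )
    adata, _ = simulate_counts(cfg)  # > 5000 cells
    X = np.asarray(adata.X.todense(), dtype=float)
    chrom = adata.var["chromosome"].to_numpy()
    ratio = X[:, chrom == "chrX"].mean() / X[:, (chrom == "chr1") | (chrom == "chr2")].mean()
    assert ratio == pytest.approx(0.5, rel=0.05)


def test_de_truth_round_trip():
    cfg = _cfg(n_de_genes=30, de_log2fc=2.0)
    adata, truth = simulate_counts(cfg)
    assert len(truth.de_genes) == 30
    assert truth.de_genes["gene_id"].is_unique
    assert set(np.abs(truth.de_genes["log2fc"])) == {2.0}
    assert truth.de_genes["gene_id"].isin(adata.var.index).all()
    # MT genes never carry drive effects
    assert (adata.var.loc[truth.de_genes["gene_id"], "chromosome"] != "MT").all()


def test_poisson_limit_variance_mean():
    """phi -> 0 gives variance/mean -> 1 for a fixed-rate gene set."""
    cfg = _cfg(
        dispersion=0.0,
        baseline_logsd=0.0,
        libsize_logsd=0.0,
        inclusion_prob={t: 1.0 for t in DEFAULT_CELL_TYPES},
        cells_per_sample_per_type={t: 150 for t in DEFAULT_CELL_TYPES},
        cell_types=("muscle",),
        stage_activity={"muscle": 1.0},
        x_dosage={"muscle": 1.0},
        mito_fraction_beta=(1e6, 1.9e7),  # essentially constant mito share
    )
    adata, _ = simulate_counts(cfg)
    X = np.asarray(adata.X.todense(), dtype=float)
    chrom = adata.var["chromosome"].to_numpy()
    auto = X[:, (chrom == "chr1") | (chrom == "chr2")]
    vmr = auto.var(axis=0, ddof=1) / np.maximum(auto.mean(axis=0), 1e-12)
    assert np.median(vmr) == pytest.approx(1.0, abs=0.1)


def test_zero_genes_on_required_chromosome_rejected():
    with pytest.raises(ValueError, match="required chromosome"):
        _cfg(genes_per_chrom={"chr1": 300, "chr2": 300, "chrX": 0, "MT": 8})


class TestSimulateSites:
    def test_haploid_single_allele_without_errors(self):
        sites = simulate_sites(5, 30, ["haploid"] * 5, depth_mean=8, error_rate=0.0, seed=2)
        covered = sites[(sites.ref_count + sites.alt_count) > 0]
        assert ((covered.ref_count == 0) | (covered.alt_count == 0)).all()

    def test_zero_het_rate_diploids_look_haploid(self):
        hap = simulate_sites(20, 40, ["haploid"] * 20, het_rate=0.0, seed=3)
        dip = simulate_sites(20, 40, ["diploid"] * 20, het_rate=0.0, seed=3)
        for df in (hap, dip):
            covered = df[(df.ref_count + df.alt_count) > 0]
            assert ((covered.ref_count == 0) | (covered.alt_count == 0)).all()

    def test_het_site_fraction_matches_binomial_expectation(self):
        """Among sites called het/hom at depth >= 2 rules, the het fraction
        matches the analytic expectation under depth ~ Poisson(6)."""
        from scipy import stats as ss

        het_rate, depth_mean = 0.5, 6.0
        sites = simulate_sites(300, 50, ["diploid"] * 300, depth_mean=depth_mean,
                               het_rate=het_rate, error_rate=0.0, seed=4)
        ref, alt = sites.ref_count.to_numpy(), sites.alt_count.to_numpy()
        hom = ((ref >= 2) & (alt == 0)) | ((alt >= 2) & (ref == 0))
        het = (ref >= 2) & (alt >= 2)
        observed = het.sum() / (het.sum() + hom.sum())
        # P(genotyped het | het site): both alleles >= 2 reads, depth d:
        # sum_d Pois(d) * P(Bin(d,.5) in [2, d-2]); hom site genotyped when d >= 2
        d = np.arange(0, 60)
        pd_ = ss.poisson.pmf(d, depth_mean)
        p_het_ok = sum(
            pd_[i] * (ss.binom.cdf(di - 2, di, 0.5) - ss.binom.cdf(1, di, 0.5))
            for i, di in enumerate(d) if di >= 4
        )
        p_hom_ok = 1 - ss.poisson.cdf(1, depth_mean)
        expected = het_rate * p_het_ok / (het_rate * p_het_ok + (1 - het_rate) * p_hom_ok)
        assert observed == pytest.approx(expected, abs=0.02)

    def test_empty_ploidy_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_sites(0, 10, [], seed=1)


class TestSimulateCoverage:
    def test_no_cnv_ratio_near_one(self):
        table, truth = simulate_coverage(n_ST=30, n_SR=30, n_genes=300, seed=9)
        assert truth.empty
        st = table.counts[table.genotype == "ST"].mean()
        sr = table.counts[table.genotype == "SR"].mean()
        assert np.median(sr / st) == pytest.approx(1.0, abs=0.05)

    def test_cnv_ratio_two_recovered(self):
        table, truth = simulate_coverage(
            n_ST=50, n_SR=27, n_genes=400, cnv_genes={7: 2.0}, seed=10
        )
        norm = table.counts.div(table.counts.sum(axis=1), axis=0)
        st = norm[table.genotype == "ST"].mean()
        sr = norm[table.genotype == "SR"].mean()
        gene = truth["gene_id"].iloc[0]
        assert sr[gene] / st[gene] == pytest.approx(2.0, rel=0.10)

    def test_fixed_seed_identical(self):
        t1, _ = simulate_coverage(n_ST=5, n_SR=5, n_genes=50, seed=1)
        t2, _ = simulate_coverage(n_ST=5, n_SR=5, n_genes=50, seed=1)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
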