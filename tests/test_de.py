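"""NB exact-test DE engine: enumeration oracles, calibration, power."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from scxa.config import DEFAULT_CELL_TYPES, SimulationConfig
from scxa.de import (
    PseudobulkDE,
    de_per_celltype,
    estimate_dispersions,
    nb_exact_test,
)
from scxa.pseudobulk import aggregate_pseudobulk
from scxa.simulate import simulate_counts
from scxa.stats import bh_adjust


def _binomial_split_oracle(s1, s, frac=0.5):
    """Two-sided conditional p under phi=0: binomial split of the total."""
    if s == 0:
        return 1.0
    x = np.arange(s + 1)
    pmf = binom.pmf(x, s, frac)
    return min(1.0, 2 * min(pmf[: s1 + 1].sum(), pmf[s1:].sum()))


class TestExactTest:
    def test_symmetric_counts_p_one(self):
        counts = np.array([[10], [10], [10], [10]])
        libs = np.full(4, 100.0)
        _, p = nb_exact_test(counts, libs, ["A", "A", "B", "B"], 0.2)
        assert p[0] == pytest.approx(1.0)

    def test_poisson_matches_enumeration_for_all_small_totals(self):
        """phi = 0, equal libraries: p equals the binomial enumeration for
        every split of every total <= 30."""
        rows = []
        for s in range(0, 31):
            for s1 in range(0, s + 1):
                rows.append((s1, s))
        counts = np.array([[s1 for s1, _ in rows], [0] * len(rows),
                           [s - s1 for s1, s in rows], [0] * len(rows)], dtype=float)
        libs = np.full(4, 1000.0)
        _, p = nb_exact_test(counts, libs, ["A", "A", "B", "B"], 0.0)
        oracle = np.array([_binomial_split_oracle(s1, s) for s1, s in rows])
        np.testing.assert_allclose(p, oracle, atol=1e-9)

    def test_log2fc_large_counts(self):
        counts = np.array([[800, 790], [810, 820], [205, 195], [198, 202]], dtype=float).reshape(4, 2)
        libs = np.full(4, 1000.0)
        lfc, _ = nb_exact_test(counts, libs, ["A", "A", "B", "B"], 0.0)
        assert lfc[0] == pytest.approx(2.0, abs=0.1)

    def test_label_swap_antisymmetric(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(20, size=(6, 40)).astype(float)
        libs = counts.sum(axis=1)
        g = np.array(["A", "A", "A", "B", "B", "B"])
        lfc1, p1 = nb_exact_test(counts, libs, g, 0.1, group_order=("A", "B"))
        lfc2, p2 = nb_exact_test(counts, libs, g, 0.1, group_order=("B", "A"))
        np.testing.assert_allclose(lfc1, -lfc2, atol=1e-9)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_all_zero_gene(self):
        counts = np.array([[0, 5], [0, 5], [0, 5], [0, 5]], dtype=float)
        lfc, p = nb_exact_test(counts, np.full(4, 10.0), ["A", "A", "B", "B"], 0.0)
        assert p[0] == 1.0 and lfc[0] == 0.0


class TestDispersions:
    def test_poisson_limit(self):
        rng = np.random.default_rng(2)
        mu = rng.lognormal(3, 1, 1500)
        y = rng.poisson(mu, size=(8, 1500))
        d = estimate_dispersions(y, y.sum(axis=1).astype(float), ["A"] * 4 + ["B"] * 4)
        assert d.common_phi < 0.05

    def test_nb_parameter_recovery(self):
        rng = np.random.default_rng(3)
        phi = 0.4
        mu = rng.lognormal(3, 1, 2000)
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu), size=(8, 2000))
        d = estimate_dispersions(y, y.sum(axis=1).astype(float), ["A"] * 4 + ["B"] * 4)
        assert 0.3 <= d.common_phi <= 0.5
        # tagwise values shrink toward common
        assert np.median(np.abs(d.tagwise_phi - d.common_phi)) < 0.3

    def test_single_gene_equals_common(self):
        y = np.array([[3], [5], [4], [6]])
        d = estimate_dispersions(y, np.full(4, 100.0), ["A", "A", "B", "B"])
        assert d.tagwise_phi[0] == d.common_phi

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match=">= 2 units"):
            estimate_dispersions(
                np.ones((3, 5)), np.full(3, 10.0), ["A", "B", "B"]
            )


class TestDEPipeline:
    def _sim(self, n_de=0, seed=31, de_chroms=None):
        cfg = SimulationConfig(
            seed=seed,
            cell_types=("primary_spermatocytes",),
            cells_per_sample_per_type={"primary_spermatocytes": 60},
            stage_activity={"primary_spermatocytes": 1.0},
            inclusion_prob={"primary_spermatocytes": 0.9},
            x_dosage={"primary_spermatocytes": 1.0},
            genes_per_chrom={"chr1": 400, "chr2": 400, "chrX": 300, "MT": 8},
            n_de_genes=n_de,
            de_log2fc=2.0,
            de_chromosomes=de_chroms,
        )
        adata, truth = simulate_counts(cfg)
        pb = aggregate_pseudobulk(adata).normalize("tmm")
        return adata, pb, truth

    def test_joint_threshold(self):
        adata, pb, _ = self._sim()
        res = de_per_celltype(adata, pb, "primary_spermatocytes")
        borderline = res[(res["fdr"] < 0.05) & (res["log2fc"].abs() <= 1.0)]
        assert (~borderline["significant"]).all()
        assert set(res.loc[res["significant"], "direction"]) <= {"SR-biased", "ST-biased"}

    def test_power_on_programmed_effects(self):
        adata, pb, truth = self._sim(n_de=40, seed=33)
        res = de_per_celltype(adata, pb, "primary_spermatocytes")
        de_in_test = truth.de_genes[truth.de_genes["gene_id"].isin(res.index)]
        detected = res.loc[de_in_test["gene_id"], "significant"]
        assert detected.mean() >= 0.8
        # direction agrees with the programmed sign
        sign_ok = np.sign(res.loc[de_in_test["gene_id"], "log2fc"]) == np.sign(
            de_in_test.set_index("gene_id")["log2fc"]
        )
        assert sign_ok[detected].all()

    def test_insufficient_replicates_skipped(self):
        adata, pb, _ = self._sim()
        keep = adata.obs["sample_id"] != "SR1"
        sub = adata[keep].copy()
        sub = sub[sub.obs["sample_id"] != "SR2"].copy()
        sub = sub[sub.obs["sample_id"] != "SR3"].copy()
        pb_sub = aggregate_pseudobulk(sub).normalize("tmm")
        with pytest.warns(UserWarning, match="replicates"):
            out = de_per_celltype(sub, pb_sub, "primary_spermatocytes")
        assert out is None

    def test_estimator_interface(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(30, size=(8, 60)))
        est = PseudobulkDE().fit(counts, np.array(["A"] * 4 + ["B"] * 4))
        assert est.results_.shape[0] == 60
        assert est.get_params()["fdr_threshold"] == 0.05


def test_fdr_calibration_null():
    """No programmed DE: mean false-discovery proportion stays below 0.10
    over 20 simulation replicates at nominal FDR 0.05 with the joint rule."""
    rng = np.random.default_rng(77)
    fdps = []
    for _ in range(20):
        phi = 0.1
        mu = rng.lognormal(3.5, 1, 400)
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu), size=(8, 400)).astype(float)
        libs = y.sum(axis=1)
        groups = np.array(["A"] * 4 + ["B"] * 4)
        disp = estimate_dispersions(y, libs, groups)
        lfc, p = nb_exact_test(y, libs, groups, disp.tagwise_phi)
        fdr = bh_adjust(p)
        sig = (fdr < 0.05) & (np.abs(lfc) > 1.0)
        fdps.append(sig.mean())  # all discoveries are false under the null
    assert np.mean(fdps) <= 0.10
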