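"""End-to-end orchestration with a reproducibility manifest.

Stages run in dependency order (qc -> msci -> dosage -> de -> enrich ->
nulls; abundance, ploidy and coverage are independent). Every run writes a
manifest recording package and dependency versions, the seed, thresholds
and SHA-256 checksums of the inputs, so any output is reproducible from the
manifest alone. A stage failure halts its dependents but preserves
completed outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import abundance_analysis
from .config import SimulationConfig
from .de import de_per_celltype
from .dosage import dosage_analysis, dosage_summary
from .enrichment import fit_enrichment_glm, pseudo_replicate_null
from .io import read_dataset, write_counts
from .msci import cell_xa_stats, inactivation_contingency_test
from .ploidy import classify_ploidy
from .pseudobulk import aggregate_pseudobulk
from .qc import QCThresholds, run_qc
from .simulate import simulate_counts, simulate_sites

log = logging.getLogger("scxa")


@dataclass
class RunConfig:
    """Pipeline configuration; all thresholds default to the documented values."""

    outdir: str = "scxa_out"
    seed: int = 0
    input_dir: str | None = None  # None -> simulate
    simulation: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    stages: tuple = ("qc", "msci", "dosage", "de", "enrich", "nulls", "abundance", "ploidy")
    nulls_repeats: int = 100
    nulls_cells_per: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "scxa",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "thresholds": {
            "qc": QCThresholds(**config.qc).__dict__,
        },
    }

    if config.input_dir is None:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
        adata, truth = simulate_counts(sim_cfg)
        simdir = out / "simulated"
        write_counts(adata, simdir)
        truth.de_genes.to_csv(simdir / "truth_de_genes.tsv", sep="\t", index=False)
        truth.x_dosage.to_csv(simdir / "truth_x_dosage.tsv", sep="\t", index=False)
        truth.ploidy.to_csv(simdir / "truth_ploidy.tsv", sep="\t", index=False)
        sim_cfg.to_yaml(simdir / "config.yaml")
        manifest["stages"]["simulate"] = "ok"
        indir = simdir
    else:
        indir = Path(config.input_dir)
        for name in ("matrix.mtx", "features.tsv", "barcodes.tsv", "cell_metadata.tsv", "gene_annotation.tsv"):
            p = indir / name
            if not p.exists():
                raise FileNotFoundError(f"required input missing: {p}")
        adata = read_dataset(indir)
    for p in sorted(indir.glob("*")):
        if p.is_file():
            manifest["inputs"][p.name] = _sha256(p)

    pb = None
    failed = set()

    def stage(name: str, deps=()):
        def wrap(fn):
            if name not in config.stages:
                return
            if any(d in failed for d in deps):
                manifest["stages"][name] = "skipped (failed dependency)"
                failed.add(name)  # block transitive dependents too
                return
            try:
                log.info("stage %s", name)
                fn()
                manifest["stages"][name] = "ok"
            except Exception as e:  # halt dependents, keep going elsewhere
                log.error("stage %s failed: %s", name, e)
                manifest["stages"][name] = f"failed: {e}"
                failed.add(name)
        return wrap

    @stage("qc")
    def _qc():
        nonlocal adata
        adata, report, n_genes = run_qc(adata, QCThresholds(**config.qc))
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        json.dump(
            {"cells_kept": adata.n_obs, "genes_removed": n_genes},
            (out / "qc_summary.json").open("w"),
        )

    @stage("msci", deps=("qc",))
    def _msci():
        stats_df = cell_xa_stats(adata)
        stats_df.to_csv(out / "cell_xa_stats.tsv", sep="\t", index=False)
        chi2, dof, p, table = inactivation_contingency_test(stats_df)
        json.dump(
            {"chi2": chi2, "df": dof, "p": p, "table": table.tolist()},
            (out / "msci_test.json").open("w"),
        )

    @stage("dosage", deps=("qc",))
    def _dosage():
        nonlocal pb
        pb = aggregate_pseudobulk(adata).normalize("tmm")
        results = dosage_analysis(adata, pb, by_class="class" in adata.var)
        dosage_summary(results).to_csv(out / "dosage_summary.tsv", sep="\t", index=False)

    @stage("de", deps=("dosage",))
    def _de():
        tables = []
        for ctype in pb.meta["cell_type"].unique():
            res = de_per_celltype(adata, pb, ctype)
            if res is not None:
                tables.append(res)
        if not tables:
            raise RuntimeError("no cell type had enough replicates for DE")
        de_all = pd.concat(tables)
        de_all.to_csv(out / "de_results.tsv", sep="\t", index=False)
        manifest["de_genes_significant"] = int(de_all["significant"].sum())

    @stage("enrich", deps=("de",))
    def _enrich():
        de_all = pd.read_csv(out / "de_results.tsv", sep="\t")
        fit = fit_enrichment_glm(
            de_all["significant"], de_all["chromosome"], de_all["cell_type"]
        )
        fit.coefficients.to_csv(out / "enrichment_coefficients.tsv", sep="\t")
        fit.lrt.to_csv(out / "enrichment_lrt.tsv", sep="\t", index=False)

    @stage("nulls", deps=("qc",))
    def _nulls():
        null = pseudo_replicate_null(
            adata,
            repeats=config.nulls_repeats,
            cells_per=config.nulls_cells_per,
            seed=config.seed,
        )
        null.percents.to_csv(out / "null_percents.tsv", sep="\t", index=False)
        null.comparison_p.to_csv(out / "null_comparison_p.tsv", sep="\t")

    @stage("abundance", deps=("qc",))
    def _abundance():
        abundance_analysis(adata.obs).to_csv(out / "abundance_fits.tsv", sep="\t", index=False)

    @stage("ploidy")
    def _ploidy():
        sites_path = indir / "sites.tsv"
        if not sites_path.exists():
            truth_ploidy = pd.read_csv(indir / "truth_ploidy.tsv", sep="\t")
            subset = truth_ploidy.iloc[: min(len(truth_ploidy), 300)]
            sites = simulate_sites(
                len(subset),
                50,
                dict(zip(subset["barcode"], subset["ploidy"])),
                seed=config.seed,
            )
        else:
            sites = pd.read_csv(sites_path, sep="\t")
        classify_ploidy(sites).to_csv(out / "ploidy_calls.tsv", sep="\t", index=False)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("manifest written to %s", manifest_path)
    return manifest
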