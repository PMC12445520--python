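"""Simulation and pipeline configuration objects (YAML round-trippable)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

#: somatic cell types come first, then the ordered germline stages
DEFAULT_CELL_TYPES = (
    "muscle",
    "early_cyst",
    "late_cyst",
    "gsc_spermatogonia",
    "primary_spermatocytes",
    "secondary_spermatocytes",
    "early_spermatids",
    "late_spermatids",
)

GERMLINE_STAGES = DEFAULT_CELL_TYPES[3:]
SOMATIC_TYPES = DEFAULT_CELL_TYPES[:3]

#: post-meiotic germline stages are haploid; everything else diploid
HAPLOID_TYPES = ("early_spermatids", "late_spermatids")


def _default_genes_per_chrom() -> dict:
    # X-rich genome: in stalk-eyed flies the X is a large fused chromosome
    return {"chr1": 2200, "chr2": 2200, "chrX": 1500, "MT": 15}


def _default_cells() -> dict:
    return {t: 150 for t in DEFAULT_CELL_TYPES}


def _default_stage_activity() -> dict:
    # multiplicative transcriptome-size factor; germline declines monotonically
    return {
        "muscle": 1.0,
        "early_cyst": 1.0,
        "late_cyst": 1.0,
        "gsc_spermatogonia": 1.5,
        "primary_spermatocytes": 1.1,
        "secondary_spermatocytes": 0.6,
        "early_spermatids": 0.3,
        "late_spermatids": 0.12,
    }


def _default_inclusion() -> dict:
    # per-stage probability that a gene is transcriptionally "on"; drives the
    # decline in expressed-gene counts across spermatogenesis (~4000 -> ~500)
    return {
        "muscle": 0.75,
        "early_cyst": 0.75,
        "late_cyst": 0.75,
        "gsc_spermatogonia": 0.85,
        "primary_spermatocytes": 0.75,
        "secondary_spermatocytes": 0.55,
        "early_spermatids": 0.35,
        "late_spermatids": 0.20,
    }


def _default_x_dosage() -> dict:
    # X-linked rate multiplier per cell type (applies to both genotypes unless
    # a "<cell_type>:<genotype>" key overrides). Early germline lacks dosage
    # compensation (X at half the autosomal rate); compensation is restored in
    # later stages; somatic cells fully compensated.
    return {
        "muscle": 1.0,
        "early_cyst": 1.0,
        "late_cyst": 1.0,
        "gsc_spermatogonia": 0.5,
        "primary_spermatocytes": 0.5,
        "secondary_spermatocytes": 1.0,
        "early_spermatids": 1.0,
        "late_spermatids": 1.0,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic testis scRNA-seq generator.

    Counts are gene-by-gene negative binomial (``var = mu + phi * mu^2``).
    The expected count of gene j in cell c of type t and genotype g is
    ``L_c * w_j / sum_k w_k`` with ``w_j = lambda_j * on_{t,j} * d_{t,g}[X]
    * 2**beta_j[SR]``; the realized library size ``L_c`` is log-normal scaled
    by the stage activity factor, and mitochondrial genes receive the cell's
    Beta-distributed mitochondrial share.
    """

    seed: int = 0
    n_samples_ST: int = 4
    n_samples_SR: int = 4
    cells_per_sample_per_type: dict = field(default_factory=_default_cells)
    cell_types: tuple = DEFAULT_CELL_TYPES
    genes_per_chrom: dict = field(default_factory=_default_genes_per_chrom)
    baseline_logmean: float = 0.0
    baseline_logsd: float = 1.0
    stage_activity: dict = field(default_factory=_default_stage_activity)
    inclusion_prob: dict = field(default_factory=_default_inclusion)
    x_dosage: dict = field(default_factory=_default_x_dosage)
    n_de_genes: int = 0
    de_log2fc: float = 2.0
    de_chromosomes: Optional[tuple] = None  # None = any non-MT chromosome
    dispersion: float = 0.15
    libsize_logmean: float = 10.3  # ~30k counts/cell before stage scaling
    libsize_logsd: float = 0.35
    mito_fraction_beta: tuple = (2.0, 38.0)  # mean ~5%
    testis_specific_frac: float = 0.3
    doublet_rate: float = 0.0

    def __post_init__(self):
        self.cell_types = tuple(self.cell_types)
        if self.de_chromosomes is not None:
            self.de_chromosomes = tuple(self.de_chromosomes)
        self.validate()

    def validate(self) -> None:
        if self.n_samples_ST < 0 or self.n_samples_SR < 0:
            raise ValueError("sample counts must be >= 0")
        if not self.cell_types or len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell_types must be non-empty and unique")
        for chrom in ("chr1", "chr2", "chrX", "MT"):
            if self.genes_per_chrom.get(chrom, 0) <= 0:
                raise ValueError(f"zero genes configured on required chromosome {chrom}")
        if any(v <= 0 for v in self.stage_activity.values()):
            raise ValueError("stage_activity must be strictly positive")
        if any(v <= 0 for v in self.x_dosage.values()):
            raise ValueError("x_dosage multipliers must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must be in [0, 1)")
        missing = [t for t in self.cell_types if t not in self.cells_per_sample_per_type]
        if missing:
            raise ValueError(f"cells_per_sample_per_type missing {missing}")

    def dosage_for(self, cell_type: str, genotype: str) -> float:
        key = f"{cell_type}:{genotype}"
        if key in self.x_dosage:
            return float(self.x_dosage[key])
        return float(self.x_dosage.get(cell_type, 1.0))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cell_types"] = list(self.cell_types)
        if d.get("de_chromosomes") is not None:
            d["de_chromosomes"] = list(d["de_chromosomes"])
        d["mito_fraction_beta"] = list(self.mito_fraction_beta)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "mito_fraction_beta" in d:
            d["mito_fraction_beta"] = tuple(d["mito_fraction_beta"])
        return cls(**d)
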