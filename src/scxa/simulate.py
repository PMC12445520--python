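"""Synthetic testis scRNA-seq generator.

Emulates the statistical structure the downstream analyses assume: eight
males (standard ST and sex-ratio drive SR genotypes), two autosomes plus an
X chromosome and a handful of mitochondrial genes, ordered germline stages
with a declining transcriptome, stage-specific X dosage factors,
drive-biased genes, overdispersed (negative binomial) counts, and
haploid/diploid allele-count profiles for ploidy calling. Every programmed
effect is returned in a truth table so recovery can be tested.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .config import HAPLOID_TYPES, SimulationConfig

__all__ = ["TruthTables", "simulate_counts", "simulate_sites", "simulate_coverage"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random sub-stream derived from one global seed."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass
class TruthTables:
    """Programmed effects of a simulation run."""

    de_genes: pd.DataFrame  # gene_id, log2fc
    x_dosage: pd.DataFrame  # cell_type, genotype, dosage
    ploidy: pd.DataFrame  # barcode, ploidy
    cnv_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "ratio"])
    )


def _gene_annotation(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = []
    for chrom in ("chr1", "chr2", "chrX", "MT"):
        chroms += [chrom] * cfg.genes_per_chrom[chrom]
    n = len(chroms)
    gene_ids = [f"g{i:05d}" for i in range(n)]
    cls = np.where(
        rng.random(n) < cfg.testis_specific_frac, "testis-specific", "broad"
    )
    cls[np.array(chroms) == "MT"] = "broad"
    return pd.DataFrame(
        {"gene_id": gene_ids, "chromosome": chroms, "class": cls}
    ).set_index("gene_id", drop=False)


def _pick_de_genes(cfg: SimulationConfig, anno: pd.DataFrame, rng) -> pd.DataFrame:
    if cfg.n_de_genes == 0:
        return pd.DataFrame(columns=["gene_id", "log2fc"])
    eligible = anno.index[anno["chromosome"] != "MT"]
    if cfg.de_chromosomes is not None:
        eligible = anno.index[anno["chromosome"].isin(cfg.de_chromosomes)]
    if cfg.n_de_genes > len(eligible):
        raise ValueError("more DE genes requested than eligible genes")
    chosen = rng.choice(eligible, size=cfg.n_de_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_de_genes)
    return pd.DataFrame({"gene_id": chosen, "log2fc": signs * cfg.de_log2fc})


def simulate_counts(config: SimulationConfig):
    """Draw a cell-by-gene count matrix and its truth tables.

    Returns ``(adata, truth)`` where ``adata`` is an :class:`anndata.AnnData`
    with integer counts (cells x genes, CSR), per-cell metadata in ``.obs``
    (sample, genotype, cell_type) and gene annotation in ``.var``.
    Identical config implies byte-identical output.
    """
    cfg = config
    cfg.validate()
    anno = _gene_annotation(cfg, substream(cfg.seed, "annotation"))
    n_genes = len(anno)
    is_mt = (anno["chromosome"] == "MT").to_numpy()
    is_x = (anno["chromosome"] == "chrX").to_numpy()

    rates_rng = substream(cfg.seed, "gene_rates")
    lam = rates_rng.lognormal(cfg.baseline_logmean, cfg.baseline_logsd, n_genes)

    de = _pick_de_genes(cfg, anno, substream(cfg.seed, "de_genes"))
    de_mult = np.ones(n_genes)
    if len(de):
        idx = anno.index.get_indexer(de["gene_id"])
        de_mult[idx] = 2.0 ** de["log2fc"].to_numpy()

    incl_rng = substream(cfg.seed, "inclusion")
    inclusion = {}
    for t in cfg.cell_types:
        pi = cfg.inclusion_prob.get(t, 1.0)
        mask = incl_rng.random(n_genes) < pi
        mask[is_mt] = True  # mitochondrial genes always transcribed
        inclusion[t] = mask

    samples = [f"ST{i+1}" for i in range(cfg.n_samples_ST)] + [
        f"SR{i+1}" for i in range(cfg.n_samples_SR)
    ]
    genotypes = {s: ("ST" if s.startswith("ST") else "SR") for s in samples}

    counts_rng = substream(cfg.seed, "counts")
    lib_rng = substream(cfg.seed, "libsizes")
    mito_rng = substream(cfg.seed, "mito")

    blocks, obs_rows = [], []
    phi = cfg.dispersion
    a_mt, b_mt = cfg.mito_fraction_beta
    p_mt = lam[is_mt] / lam[is_mt].sum()
    for sample in samples:
        geno = genotypes[sample]
        for ctype in cfg.cell_types:
            n_cells = int(cfg.cells_per_sample_per_type[ctype])
            if n_cells == 0:
                continue
            w = lam * inclusion[ctype]
            w = np.where(is_x, w * cfg.dosage_for(ctype, geno), w)
            if geno == "SR":
                w = w * de_mult
            w_auto = w.copy()
            w_auto[is_mt] = 0.0
            p_non = w_auto / w_auto.sum()

            act = cfg.stage_activity.get(ctype, 1.0)
            lib = lib_rng.lognormal(cfg.libsize_logmean, cfg.libsize_logsd, n_cells) * act
            mfrac = mito_rng.beta(a_mt, b_mt, n_cells)

            mean = np.empty((n_cells, n_genes))
            mean[:, ~is_mt] = np.outer(lib * (1 - mfrac), p_non[~is_mt])
            mean[:, is_mt] = np.outer(lib * mfrac, p_mt)
            if phi > 0:
                shape = 1.0 / phi
                mean = mean * counts_rng.gamma(shape, 1.0 / shape, size=mean.shape)
            block = counts_rng.poisson(mean)
            blocks.append(sparse.csr_matrix(block.astype(np.int64)))
            for i in range(n_cells):
                obs_rows.append((f"{sample}_{ctype}_{i:04d}", sample, geno, ctype))

    X = sparse.vstack(blocks, format="csr")
    obs = pd.DataFrame(
        obs_rows, columns=["barcode", "sample_id", "genotype", "cell_type"]
    ).set_index("barcode", drop=False)
    obs["cell_type"] = pd.Categorical(obs["cell_type"], categories=cfg.cell_types)

    if cfg.doublet_rate > 0:
        dbl_rng = substream(cfg.seed, "doublets")
        n_dbl = int(round(cfg.doublet_rate * X.shape[0]))
        pairs = dbl_rng.choice(X.shape[0], size=(n_dbl, 2))
        dbl = X[pairs[:, 0]] + X[pairs[:, 1]]
        X = sparse.vstack([X, dbl], format="csr")
        extra = obs.iloc[pairs[:, 0]].copy()
        extra["barcode"] = [f"doublet_{i:04d}" for i in range(n_dbl)]
        extra.index = extra["barcode"]
        obs = pd.concat([obs, extra])
        obs["is_doublet"] = [False] * (len(obs) - n_dbl) + [True] * n_dbl

    adata = ad.AnnData(X=X, obs=obs, var=anno.copy())

    dosage_rows = [
        (t, g, cfg.dosage_for(t, g)) for t in cfg.cell_types for g in ("ST", "SR")
    ]
    truth = TruthTables(
        de_genes=de.reset_index(drop=True),
        x_dosage=pd.DataFrame(dosage_rows, columns=["cell_type", "genotype", "dosage"]),
        ploidy=pd.DataFrame(
            {
                "barcode": obs.index,
                "ploidy": [
                    "haploid" if t in HAPLOID_TYPES else "diploid"
                    for t in obs["cell_type"]
                ],
            }
        ),
    )
    return adata, truth


def simulate_sites(
    n_cells: int,
    n_sites: int,
    ploidy_map,
    depth_mean: float = 6.0,
    het_rate: float = 0.5,
    error_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell allele counts at polymorphic sites for ploidy calling.

    ``ploidy_map`` maps barcode -> {'haploid','diploid'} (or is a sequence of
    length ``n_cells``). Read depth per site is Poisson; haploid cells carry
    one allele (sequencing errors at ``error_rate`` land on the other);
    diploid cells are heterozygous at ``het_rate`` with reads split
    binomially. Returns a long table (barcode, site_id, ref_count, alt_count).
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if not 0 <= het_rate <= 1 or not 0 <= error_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    if isinstance(ploidy_map, dict):
        if not ploidy_map:
            raise ValueError("empty ploidy_map")
        barcodes = list(ploidy_map)
        ploidies = [ploidy_map[b] for b in barcodes]
    else:
        ploidies = list(ploidy_map)
        if not ploidies:
            raise ValueError("empty ploidy_map")
        if len(ploidies) != n_cells:
            raise ValueError("ploidy_map length must equal n_cells")
        barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    bad = set(ploidies) - {"haploid", "diploid"}
    if bad:
        raise ValueError(f"unknown ploidy labels: {sorted(bad)}")

    rng = substream(seed, "sites")
    rows = []
    for barcode, ploidy in zip(barcodes, ploidies):
        depth = rng.poisson(depth_mean, n_sites)
        true_ref = rng.random(n_sites) < 0.5  # which allele the haplotype carries
        if ploidy == "diploid":
            het = rng.random(n_sites) < het_rate
        else:
            het = np.zeros(n_sites, dtype=bool)
        ref = np.where(
            het,
            rng.binomial(depth, 0.5),
            np.where(
                true_ref,
                depth - rng.binomial(depth, error_rate),
                rng.binomial(depth, error_rate),
            ),
        )
        alt = depth - ref
        for j in range(n_sites):
            rows.append((barcode, f"site{j:05d}", int(ref[j]), int(alt[j])))
    return pd.DataFrame(rows, columns=["barcode", "site_id", "ref_count", "alt_count"])


@dataclass
class CoverageTable:
    """Per-individual per-gene DNA read counts with genotype labels."""

    counts: pd.DataFrame  # individuals x genes
    genotype: pd.Series  # per individual, ST or SR

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("coverage counts must be nonnegative")
        if self.genotype.value_counts().min() < 2:
            raise ValueError("need >= 2 individuals per genotype")


def simulate_coverage(
    n_ST: int = 50,
    n_SR: int = 27,
    n_genes: int = 2000,
    cnv_genes: dict | None = None,
    depth_params: dict | None = None,
    seed: int = 0,
):
    """DNA read-count table per individual; CNV genes scaled in SR.

    ``cnv_genes`` maps gene index (int) or gene id -> coverage ratio (SR/ST).
    Returns ``(CoverageTable, truth)`` with truth listing the programmed
    ratios.
    """
    cnv_genes = cnv_genes or {}
    p = {"depth_mean": 100.0, "dispersion": 0.05, "logsd": 0.6, "libsize_logsd": 0.15}
    p.update(depth_params or {})
    if any(r <= 0 for r in cnv_genes.values()):
        raise ValueError("cnv gene ratios must be > 0")

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    idx_of = {g: i for i, g in enumerate(gene_ids)}
    ratio = np.ones(n_genes)
    for key, r in cnv_genes.items():
        i = idx_of[key] if isinstance(key, str) else int(key)
        ratio[i] = r

    rng = substream(seed, "coverage")
    mu_g = rng.lognormal(np.log(p["depth_mean"]), p["logsd"], n_genes)
    n = n_ST + n_SR
    sf = rng.lognormal(0.0, p["libsize_logsd"], n)
    geno = np.array(["ST"] * n_ST + ["SR"] * n_SR)
    mean = np.outer(sf, mu_g)
    mean[geno == "SR"] *= ratio
    phi = p["dispersion"]
    if phi > 0:
        mean = mean * rng.gamma(1.0 / phi, phi, size=mean.shape)
    counts = rng.poisson(mean)
    individuals = [f"ST_{i:03d}" for i in range(n_ST)] + [
        f"SR_{i:03d}" for i in range(n_SR)
    ]
    table = CoverageTable(
        counts=pd.DataFrame(counts, index=individuals, columns=gene_ids),
        genotype=pd.Series(geno, index=individuals, name="genotype"),
    )
    truth = pd.DataFrame(
        {
            "gene_id": [gene_ids[i] for i in range(n_genes) if ratio[i] != 1.0],
            "ratio": [ratio[i] for i in range(n_genes) if ratio[i] != 1.0],
        }
    )
    return table, truth
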