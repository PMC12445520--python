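"""Haploid/diploid cell classification from per-cell allele counts.

Post-meiotic germ cells are haploid and can carry only one allele at any
site, so the fraction of genotyped sites that are homozygous separates
them from diploid cells. A site is called homozygous when one allele has
at least two reads and the other none, heterozygous when both alleles have
at least two reads, and ungenotyped otherwise; cells need at least ten
genotyped sites to be classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

MIN_SITES = 10
HOM_DEPTH = 2
HET_DEPTH_EACH = 2
HOM_FRAC_CUTOFF = 1.0


def call_site(ref_count, alt_count, hom_depth: int = HOM_DEPTH, het_depth_each: int = HET_DEPTH_EACH):
    """Genotype one site (vectorized): 'homozygous', 'heterozygous' or 'ungenotyped'.

    Homozygous: one allele with >= hom_depth reads, the other with 0.
    Heterozygous: both alleles with >= het_depth_each reads. A 2/1 split is
    neither and stays ungenotyped.
    """
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("allele counts must be >= 0")
    hom = ((ref >= hom_depth) & (alt == 0)) | ((alt >= hom_depth) & (ref == 0))
    het = (ref >= het_depth_each) & (alt >= het_depth_each)
    out = np.where(hom, "homozygous", np.where(het, "heterozygous", "ungenotyped"))
    return out if out.ndim else out.item()


@dataclass
class PloidyCall:
    barcode: str
    n_genotyped: int
    frac_homozygous: float
    call: str  # haploid | diploid | unclassified


def classify_ploidy(
    sites: pd.DataFrame,
    min_sites: int = MIN_SITES,
    hom_frac_cutoff: float = HOM_FRAC_CUTOFF,
    hom_depth: int = HOM_DEPTH,
    het_depth_each: int = HET_DEPTH_EACH,
) -> pd.DataFrame:
    """Classify every cell in a long site table.

    ``sites`` columns: barcode, site_id, ref_count, alt_count. Cells with
    fewer than ``min_sites`` genotyped sites are 'unclassified'; haploid iff
    the homozygous fraction is >= ``hom_frac_cutoff``, else diploid.
    """
    d = sites.copy()
    if d.duplicated(["barcode", "site_id"]).any():
        raise ValueError("duplicate site_id within a cell")
    d["gt"] = call_site(
        d["ref_count"].to_numpy(), d["alt_count"].to_numpy(), hom_depth, het_depth_each
    )
    rows = []
    for barcode, grp in d.groupby("barcode", sort=False):
        genotyped = grp[grp["gt"] != "ungenotyped"]
        n = len(genotyped)
        frac = float((genotyped["gt"] == "homozygous").mean()) if n else np.nan
        if n < min_sites:
            call = "unclassified"
        elif frac >= hom_frac_cutoff:
            call = "haploid"
        else:
            call = "diploid"
        rows.append((barcode, n, frac, call))
    return pd.DataFrame(
        rows, columns=["barcode", "n_genotyped", "frac_homozygous", "call"]
    ).set_index("barcode", drop=False)


class PloidyClassifier(BaseEstimator, ClassifierMixin):
    """Estimator wrapper over the homozygosity-fraction ploidy caller."""

    def __init__(
        self,
        min_sites: int = MIN_SITES,
        hom_frac_cutoff: float = HOM_FRAC_CUTOFF,
        hom_depth: int = HOM_DEPTH,
        het_depth_each: int = HET_DEPTH_EACH,
    ):
        self.min_sites = min_sites
        self.hom_frac_cutoff = hom_frac_cutoff
        self.hom_depth = hom_depth
        self.het_depth_each = het_depth_each

    def fit(self, X: pd.DataFrame, y=None):
        self.calls_ = classify_ploidy(
            X, self.min_sites, self.hom_frac_cutoff, self.hom_depth, self.het_depth_each
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        calls = classify_ploidy(
            X, self.min_sites, self.hom_frac_cutoff, self.hom_depth, self.het_depth_each
        )
        return calls["call"].to_numpy()
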