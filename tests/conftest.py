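import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from scxa.config import DEFAULT_CELL_TYPES, SimulationConfig
from scxa.simulate import simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """Small default simulation shared across read-only tests."""
    cfg = SimulationConfig(
        seed=11,
        cells_per_sample_per_type={t: 30 for t in DEFAULT_CELL_TYPES},
        genes_per_chrom={"chr1": 500, "chr2": 500, "chrX": 350, "MT": 10},
    )
    return simulate_counts(cfg)


@pytest.fixture()
def tiny_adata():
    """Hand-built 4-cell x 6-gene AnnData with known structure."""
    import anndata as ad

    counts = np.array(
        [
            [5, 0, 2, 3, 1, 20],
            [0, 1, 0, 0, 0, 0],
            [2, 2, 2, 2, 2, 2],
            [10, 10, 10, 10, 0, 80],
        ]
    )
    obs = pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2", "s2"],
            "genotype": ["ST", "ST", "SR", "SR"],
            "cell_type": ["muscle", "muscle", "late_spermatids", "late_spermatids"],
        },
        index=[f"c{i}" for i in range(4)],
    )
    var = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(6)],
            "chromosome": ["chr1", "chr1", "chr2", "chrX", "chrX", "MT"],
        },
        index=[f"g{i}" for i in range(6)],
    )
    return ad.AnnData(X=counts, obs=obs, var=var)
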