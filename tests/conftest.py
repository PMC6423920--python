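import numpy as np
import pandas as pd
import pytest

from gwasnet import simulate as sim
from gwasnet.io import GwasTable


@pytest.fixture(scope="session")
def small_layout():
    return sim.simulate_genome(n_genes=50, snps_per_gene=5)


@pytest.fixture(scope="session")
def small_ld(small_layout):
    return sim.layout_ld(small_layout, rho=0.5)


@pytest.fixture(scope="session")
def null_gwas(small_layout, small_ld):
    truth = sim.make_truth(small_layout, [])
    return sim.simulate_gwas(small_layout, small_ld, truth, n=10_000, seed=11)


@pytest.fixture()
def tiny_gwas():
    """Hand-built 4-SNP table for boundary tests."""
    df = pd.DataFrame(
        {
            "snp_id": ["A", "B", "C", "D"],
            "chrom": ["1", "1", "1", "2"],
            "pos": [100_000, 150_000, 170_001, 50_000],
            "p": [1e-8, 1e-4, 0.2, 0.9],
            "maf": [0.30, 0.005, 0.01, 0.45],
        }
    )
    return GwasTable(df)


def make_gwas(p_values, prefix="s"):
    """GwasTable with given p-values at arbitrary positions."""
    k = len(p_values)
    return GwasTable(
        pd.DataFrame(
            {
                "snp_id": [f"{prefix}{i}" for i in range(k)],
                "chrom": "1",
                "pos": np.arange(1, k + 1) * 1000,
                "p": np.asarray(p_values, dtype=float),
            }
        )
    )
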