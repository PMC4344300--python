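import numpy as np
import pandas as pd
import pytest

from telomethyl.positional_stats import ChromosomeLayout
from telomethyl.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_samples=24,
        n_chromosomes=2,
        chrom_length=15_000_000,
        n_genes=60,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """(layout, genes, imprinted, samples, matrix, truth) for a small cohort."""
    return simulate_study(small_config)


@pytest.fixture()
def toy_layout() -> ChromosomeLayout:
    return ChromosomeLayout.from_dict(
        {
            "chr1": (10_000_000, 4_800_000, 5_200_000),
            "chr2": (12_000_000, 5_500_000, 6_000_000),
            "chrNoCen": (9_000_000,),
        }
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
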