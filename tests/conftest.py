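import numpy as np
import pandas as pd
import pytest

from poolscan.io_formats import PoolMetadata
from poolscan.synthetic_data import TruthConfig, build_truth, sample_pools


@pytest.fixture
def metadata_two_pops() -> PoolMetadata:
    """Two populations (one per mode), two replicate libraries each."""
    return PoolMetadata(
        pd.DataFrame(
            {
                "library_id": ["CP1_L1", "CP1_L2", "OP1_L1", "OP1_L2"],
                "population_id": ["CP1", "CP1", "OP1", "OP1"],
                "mode": ["CP", "CP", "OP", "OP"],
                "n_lineages": [20, 20, 14, 14],
            }
        )
    )


@pytest.fixture(scope="session")
def small_truth_config() -> TruthConfig:
    """Desk-scale study: 2 chromosomes of 500 kb, 100-kb candidate block."""
    return TruthConfig(
        n_chromosomes=2,
        chrom_length=500_000,
        candidate_interval=("X", 200_000, 300_000),
        n_candidate_genes=10,
        snp_density=0.005,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_truth_config):
    return build_truth(small_truth_config)


@pytest.fixture(scope="session")
def small_pools(small_truth, small_truth_config):
    sync, meta = sample_pools(small_truth, small_truth_config)
    return sync, meta
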