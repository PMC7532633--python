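import numpy as np
import pytest

from pmdscan import SimConfig, make_methylome, simulate_methylome


@pytest.fixture
def tiny_methylome():
    """Hand-built two-chromosome methylome with known counts."""
    return make_methylome(
        {"chr1": 3000, "chr2": 2000},
        {
            "chr1": {
                "pos": np.array([100, 999, 1000, 1500]),
                "level": np.array([0.5, 1.0, 0.0, 1.0]),
                "coverage": np.array([4, 2, 3, 1]),
            },
            "chr2": {
                "pos": np.array([10, 700]),
                "level": np.array([0.25, 0.0]),
                "coverage": np.array([4, 0]),
            },
        },
    )


@pytest.fixture(scope="session")
def pc_sample():
    """One deep PMD-containing simulated methylome (2 Mb, 30x)."""
    cfg = SimConfig(chrom_sizes={"chr1": 2_000_000}, seed=11)
    return simulate_methylome(cfg)
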