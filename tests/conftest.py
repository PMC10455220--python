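import numpy as np
import pandas as pd
import pytest

from synergyseek.io import CountsMatrix
from synergyseek.simulate import SimConfig, simulate_counts


@pytest.fixture
def tiny_counts() -> CountsMatrix:
    """3 genes x 4 samples, two cell lines, DMSO + DNR."""
    counts = pd.DataFrame(
        {
            "A_DMSO_r1": [10, 20, 30],
            "A_DNR_r1": [40, 20, 5],
            "B_DMSO_r1": [12, 18, 28],
            "B_DNR_r1": [11, 19, 29],
        },
        index=["G1", "G2", "G3"],
    )
    meta = pd.DataFrame(
        {
            "cell_line": ["A", "A", "B", "B"],
            "treatment": ["DMSO", "DNR", "DMSO", "DNR"],
            "replicate": [1, 1, 1, 1],
        },
        index=counts.columns,
    )
    return CountsMatrix(counts=counts, meta=meta)


@pytest.fixture(scope="session")
def default_sim():
    """One default-config synthetic dataset shared by recovery tests."""
    config = SimConfig(seed=1)
    cm, truth = simulate_counts(config)
    return config, cm, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
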