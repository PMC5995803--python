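import numpy as np
import pandas as pd
import pytest

from brainsig.io import LabeledCountMatrix
from brainsig.simulate import SimulationConfig, simulate_cells


@pytest.fixture
def tiny_matrix() -> LabeledCountMatrix:
    """3 genes x 4 samples, two cell types, hand-checkable."""
    counts = pd.DataFrame(
        {
            "a1": [10, 0, 3],
            "a2": [12, 0, 5],
            "b1": [1, 7, 4],
            "b2": [3, 9, 6],
        },
        index=["g1", "g2", "g3"],
    )
    labels = pd.Series(["AST", "AST", "NEU", "NEU"], index=counts.columns)
    return LabeledCountMatrix(counts, labels)


@pytest.fixture(scope="session")
def sim_default():
    """The standard simulated study: planted markers, default conditions."""
    cfg = SimulationConfig(seed=5)
    m, truth = simulate_cells(cfg)
    return cfg, m, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
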