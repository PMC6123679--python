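import numpy as np
import pandas as pd
import pytest

from sbevol.containers import CountMatrix
from sbevol.simulate import SimConfig


@pytest.fixture
def toy_count_matrix() -> CountMatrix:
    counts = pd.DataFrame(
        {
            "F1": [100, 10, 50, 0, 5],
            "F2": [120, 12, 45, 1, 6],
            "M1": [90, 200, 55, 0, 4],
            "M2": [110, 180, 60, 0, 7],
        },
        index=[f"g{i}" for i in range(5)],
    )
    samples = pd.DataFrame(
        {"sex": ["female", "female", "male", "male"], "tissue": "gonad"},
        index=counts.columns,
    )
    return CountMatrix(counts, samples)


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_genes=200, n_samples_per_group=3, library_size=1e6)
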