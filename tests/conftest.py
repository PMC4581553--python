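import numpy as np
import pandas as pd
import pytest

from heteroseq import CountTable


@pytest.fixture
def small_table() -> CountTable:
    """Three-gene count table with easy hand arithmetic."""
    genes = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "length_bp": [1000, 500, 2000],
            "count_P1": [100, 0, 40],
            "count_P2": [100, 10, 0],
            "count_F1": [100, 5, 20],
        }
    )
    return CountTable(genes, {"P1": 1_000_000, "P2": 1_000_000, "F1": 1_000_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
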