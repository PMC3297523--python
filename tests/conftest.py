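import numpy as np
import pandas as pd
import pytest

from epiherit import SimConfig, simulate


@pytest.fixture
def small_cfg():
    """A fast, fully featured configuration for end-to-end checks."""
    return SimConfig(
        seed=11,
        n_genes=300,
        n_de_genes=50,
        n_promoters_tiled=60,
        n_dm_promoters=30,
        n_sweeps=25,
        genome=(("chr1", 40_000_000), ("chr2", 30_000_000), ("chr3", 20_000_000)),
    )


@pytest.fixture
def small_dataset(small_cfg):
    return simulate(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def probe_table_from_ma(m: np.ndarray, a: np.ndarray) -> pd.DataFrame:
    """Minimal probe table with given M and A matrices (probes x samples)."""
    n, k = m.shape
    table = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 100,
            "end": np.arange(n) * 100 + 50,
            "promoter_id": "prom0",
        }
    )
    for j in range(k):
        table[f"M_s{j}"] = m[:, j]
        table[f"A_s{j}"] = a[:, j]
    return table
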