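import numpy as np
import pandas as pd
import pytest

from dosagefold import FeatureTable, SimulationConfig


def make_table(values, strains, ploidies, replicates=None, is_qc=None, platform="ESI-", scale="raw"):
    """Build a FeatureTable from a 2-D array and per-sample labels."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    replicates = replicates or list(range(1, n + 1))
    is_qc = is_qc or [False] * n
    ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "strain": strains,
            "ploidy": ploidies,
            "replicate": replicates,
            "is_qc": is_qc,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    data = pd.DataFrame(
        values, index=meta.index, columns=[f"F{j}" for j in range(values.shape[1])]
    )
    return FeatureTable(data, meta, platform, scale=scale)


def two_group_table(group_a, group_b, strain="S1"):
    """One strain, two cytotypes; group_a -> 2n rows, group_b -> 4n rows."""
    values = np.vstack([group_a, group_b])
    n_a, n_b = len(group_a), len(group_b)
    return make_table(
        values,
        strains=[strain] * (n_a + n_b),
        ploidies=["2n"] * n_a + ["4n"] * n_b,
        replicates=list(range(1, n_a + 1)) + list(range(1, n_b + 1)),
    )


@pytest.fixture
def small_config():
    return SimulationConfig(seed=11, n_features=300)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
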