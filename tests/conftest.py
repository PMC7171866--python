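import numpy as np
import pandas as pd
import pytest

from assemblage import OtuTable, SampleMetadata
from assemblage.tree import read_tree


@pytest.fixture
def toy_table():
    """Three stations, four taxa, hand-sized counts."""
    return OtuTable(
        ["S1", "S2", "S3"],
        ["A", "B", "C", "D"],
        np.array([[6, 2, 0, 2], [2, 2, 2, 4], [0, 0, 5, 5]]),
    )


@pytest.fixture
def toy_tree():
    return read_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture
def toy_metadata():
    df = pd.DataFrame(
        {
            "latitude": [0.0, 0.0, 0.0],
            "longitude": [0.0, 5.0, 10.0],
            "cruise_order": [1, 2, 3],
            "temperature": [18.0, 22.0, 26.0],
            "salinity": [35.1, 35.3, 35.0],
            "province": ["P1", "P1", "P2"],
        },
        index=["S1", "S2", "S3"],
    )
    return SampleMetadata(df, env_vars=["temperature", "salinity"],
                          group_vars=["province"])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_table(rng, n_samples=6, n_taxa=12, depth=500):
    pool = rng.dirichlet(np.ones(n_taxa))
    counts = np.vstack([rng.multinomial(depth, pool) for _ in range(n_samples)])
    # guard against empty samples/taxa in tiny draws
    counts[:, 0] += 1
    return OtuTable([f"s{i}" for i in range(n_samples)],
                    [f"t{j}" for j in range(n_taxa)], counts)
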