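import numpy as np
import pandas as pd
import pytest

from ecoassembly.core_data import (
    CommunityTable,
    SampleMetadata,
    tree_from_newick,
)
from ecoassembly.synthetic_data import ScenarioConfig, simulate_scenario


@pytest.fixture
def tiny_table() -> CommunityTable:
    """3 taxa x 2 samples, column sums (10, 12)."""
    return CommunityTable(
        ["OTU_A", "OTU_B", "OTU_C"],
        ["s1", "s2"],
        np.array([[6, 2], [2, 2], [2, 8]]),
    )


@pytest.fixture
def tiny_tree():
    """((A:1,B:1):1,C:2); — d(A,B)=2, d(A,C)=d(B,C)=4."""
    return tree_from_newick("((OTU_A:1,OTU_B:1):1,OTU_C:2);")


@pytest.fixture
def transect_meta() -> SampleMetadata:
    n = 8
    return SampleMetadata(
        pd.DataFrame(
            {
                "latitude": np.linspace(-20, 50, n),
                "longitude": np.full(n, -170.0),
                "layer": ["surface", "DCM"] * (n // 2),
                "temperature": np.linspace(28, 4, n),
                "nitrate": np.linspace(0.1, 8.0, n),
            },
            index=pd.Index([f"s{i + 1}" for i in range(n)], name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def selection_bundle():
    """Small selection-mode metacommunity shared across tests."""
    config = ScenarioConfig(
        n_taxa=60,
        n_samples=16,
        reads_per_sample=600,
        mode="selection",
        sigma_w=2.0,
        sigma2=1.0,
        seed=7,
    )
    table, tree, meta, truth = simulate_scenario(config)
    return table.drop_zero_taxa(), tree, meta, truth


@pytest.fixture(scope="session")
def neutral_bundle():
    config = ScenarioConfig(
        n_taxa=60,
        n_samples=16,
        reads_per_sample=600,
        mode="neutral",
        m=0.3,
        seed=8,
    )
    table, tree, meta, truth = simulate_scenario(config)
    return table.drop_zero_taxa(), tree, meta, truth
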