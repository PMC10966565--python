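import numpy as np
import pandas as pd
import pytest

from oscillome.source import Parcellation
from oscillome.synth import SynthCohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Desk-scale cohort: 5 regions, 10 s, enough for shape/determinism checks."""
    return SynthCohortConfig(
        n_per_group={"HC": 3, "PKD": 3}, duration=10.0, n_regions=5, seed=7
    )


def single_vertex_parcellation(region_names, network_labels):
    """One vertex per region, no merging — parcellate() becomes (sign-aligned) identity."""
    table = pd.DataFrame(
        {
            "region": list(region_names),
            "network": list(network_labels),
            "vertex_ids": [[i] for i in range(len(region_names))],
            "merge_into": [None] * len(region_names),
        }
    )
    return Parcellation(table=table, min_vertices=1)
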