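import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import trustcpm as tc

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def toy_atlas() -> tc.Atlas:
    """16-node atlas spanning all five networks (120 edges)."""
    rows = []
    for nw, size in zip(tc.NETWORKS, (4, 3, 4, 3, 2)):
        for k in range(size):
            rows.append({"name": f"{nw}{k}", "x": k, "y": -k, "z": 2 * k,
                         "network": nw})
    return tc.Atlas(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def toy_dataset(toy_atlas) -> tc.SyntheticDataset:
    """Small planted-signal dataset on the toy atlas (20 subjects)."""
    params = tc.SyntheticParams(n_subjects=20, n_signal_edges=4,
                                edge_effect=0.6, atlas=toy_atlas, seed=5)
    return tc.generate_dataset(params)


@pytest.fixture(scope="session")
def toy_behavior(toy_dataset) -> pd.DataFrame:
    return toy_dataset.behavior


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
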