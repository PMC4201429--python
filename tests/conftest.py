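import numpy as np
import pandas as pd
import pytest

import tempophylo as tp


@pytest.fixture(scope="session")
def default_study():
    """The standard simulated campaign (seed 1): tree, guilds, records."""
    return tp.default_fixture(seed=1)


@pytest.fixture(scope="session")
def default_distances(default_study):
    phylo, _, _ = default_study
    return tp.node_count_distance_matrix(phylo)


@pytest.fixture(scope="session")
def ten_tip_tree():
    return tp.simulate_tree(10, seed=42)


@pytest.fixture()
def toy_records():
    return pd.DataFrame(
        {
            "year": [2001, 2001, 2001, 2002, 2002],
            "month": [1, 2, 3, 3, 3],
            "sample_id": ["a", "b", "c", "d", "d"],
            "species_id": ["A", "B", "A", "B", "C"],
            "count": [2, 1, 5, 1, 3],
        }
    )


def random_yule(n_tips: int, seed: int) -> tp.Phylogeny:
    return tp.simulate_tree(n_tips, seed=seed)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
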