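import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from batemeta.phylo import DivergenceMatrix, phylo_correlation
from batemeta.simulate import SimulationConfig, simulate_meta_dataset, simulate_tree


@pytest.fixture(scope="session")
def three_taxon_matrix():
    return DivergenceMatrix(
        ["A", "B", "C"], np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]])
    )


@pytest.fixture(scope="session")
def small_tree():
    return simulate_tree(15, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_tree):
    """25 effect sizes from 15 species in 18 studies, with ground truth."""
    config = SimulationConfig(n_species=15, n_studies=18, n_effects=25, seed=11)
    records, truth = simulate_meta_dataset(config, small_tree, seed=11)
    return records, truth, phylo_correlation(small_tree)


@pytest.fixture(scope="session")
def literature_like_dataset():
    """Dataset with the compiled-literature shape: 120 effects / 84 studies / 77 species."""
    config = SimulationConfig(seed=3)
    tree = simulate_tree(config.n_species, seed=3)
    records, truth = simulate_meta_dataset(config, tree, seed=3)
    return records, truth, phylo_correlation(tree)


@pytest.fixture()
def toy_records():
    """Two independent estimates with known inverse-variance weighted mean 0.28."""
    return pd.DataFrame(
        {
            "effect_id": ["e1", "e2"],
            "study_id": ["s1", "s2"],
            "species": ["spA", "spB"],
            "r": [0.2, 0.6],
            "n": [20, 20],
            "var_r": [0.01, 0.04],
        }
    )
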