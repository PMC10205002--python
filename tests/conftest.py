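import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from glandcov import SimConfig, Tree, simulate_epg_dataset, simulate_tree


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — root-to-tip distance 2 everywhere."""
    return Tree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree8():
    from oracles import star_newick

    return Tree.from_newick(star_newick([f"t{i}" for i in range(8)], t=1.0))


@pytest.fixture
def yule_tree():
    return simulate_tree(12, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """A small full synthetic study shared across pipeline tests."""
    return simulate_epg_dataset(
        SimConfig(n_taxa=12, n_bins=40, effect_bins=(10, 11, 12), seed=11)
    )
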