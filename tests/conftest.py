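import numpy as np
import pytest

from divergrass.bisse import BisseParams
from divergrass.phylo_core import TimeTree, TipData
from divergrass.synthetic_data import (
    DEFAULT_BISSE_PARAMS,
    SimulationConfig,
    simulate_bisse_tree,
)


@pytest.fixture
def three_tip_tree() -> TimeTree:
    return TimeTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry() -> tuple[TimeTree, TipData]:
    tree = TimeTree.from_newick("(A:1,B:1);")
    tips = TipData.from_dict({"A": 0, "B": 0})
    return tree, tips


@pytest.fixture(scope="session")
def sim_tree_100() -> tuple[TimeTree, TipData]:
    """One 100-tip state-dependent simulation shared across tests."""
    cfg = SimulationConfig(seed=11, params=DEFAULT_BISSE_PARAMS, target_tips=100)
    return simulate_bisse_tree(cfg)


@pytest.fixture(scope="session")
def sim_tree_50() -> tuple[TimeTree, TipData]:
    cfg = SimulationConfig(seed=23, params=DEFAULT_BISSE_PARAMS, target_tips=50)
    return simulate_bisse_tree(cfg)


@pytest.fixture
def random_params() -> BisseParams:
    rng = np.random.default_rng(77)
    lam = rng.uniform(0.1, 0.6, 2)
    mu = rng.uniform(0.0, 0.3, 2)
    q = rng.uniform(0.01, 0.1, 2)
    return BisseParams(lam[0], lam[1], mu[0], mu[1], q[0], q[1])
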