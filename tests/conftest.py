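import numpy as np
import pytest

from fadesat import FAProfile, read_newick
from fadesat.simulate import SimulationConfig, simulate_tree


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the standard worked example."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def reference_profile():
    """Profile whose Δ9-DI is 37/20 = 1.85 by hand evaluation."""
    return FAProfile(
        "reference",
        {
            "14:1ω5": 2.0, "16:1ω7": 10.0, "16:1ω9": 1.0,
            "18:1ω9": 20.0, "18:1ω7": 4.0,
            "14:0": 3.0, "16:0": 15.0, "18:0": 2.0,
            "22:6ω3": 43.0,
        },
    )


def random_tree(seed: int, n_tips: int):
    """Small seeded Yule tree for oracle comparisons."""
    return simulate_tree(SimulationConfig(seed=seed, n_tips=n_tips))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
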