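import numpy as np
import pytest
from hypothesis import settings

import carapace as cp
from carapace import simulate as sim

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def cherry():
    return cp.parse_newick("(A:1.0,B:1.0);")


@pytest.fixture
def small_tree():
    return cp.parse_newick("((A:1.0,B:1.0):0.5,C:1.5);")


@pytest.fixture
def star_tree():
    return cp.parse_newick("(A:2.0,B:2.0,C:2.0,D:2.0,E:2.0);")


@pytest.fixture
def yule16():
    return sim.sim_tree(16, seed=42)


def random_trees(n_trees, max_tips=8, min_tips=3, seed=0, root_age=50.0):
    """Deterministic stream of small Yule trees for oracle comparisons."""
    rng = np.random.Generator(np.random.PCG64(seed))
    for k in range(n_trees):
        n = int(rng.integers(min_tips, max_tips + 1))
        yield sim.sim_tree(n, seed=seed * 1000 + k + 1, root_age=root_age)


def random_traits(tree, rng, scale=1.0):
    vals = {lab: float(rng.normal(0, scale)) for lab in tree.tip_labels}
    return cp.TraitTable(vals, trait="x", scale="log2")
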