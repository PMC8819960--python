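import numpy as np
import pandas as pd
import pytest

import rftest as rt
from rftest.simulate import _random_binary_tree


@pytest.fixture(scope="session")
def small_tree():
    return rt.parse_newick("((A,B),C);")


@pytest.fixture(scope="session")
def random_tree_factory():
    """Factory for random binary trees with labeled leaves."""

    def make(n_leaves: int, seed: int) -> rt.PhyloTree:
        rng = np.random.default_rng(seed)
        labels = [f"L{i:03d}" for i in range(n_leaves)]
        return _random_binary_tree(labels, rng)

    return make


@pytest.fixture(scope="session")
def community():
    """One medium-sized synthetic community shared across tests."""
    return rt.synth_community(n=50, p=200, depth=20000, seed=42)


@pytest.fixture(scope="session")
def small_community():
    """A small, fast community for pipeline tests."""
    return rt.synth_community(n=30, p=40, depth=500, seed=7)


def random_counts(tree: rt.PhyloTree, n: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.integers(0, 20, size=(n, tree.n_leaves)),
        index=[f"S{i}" for i in range(n)],
        columns=list(tree.leaves),
    ).astype(float)
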