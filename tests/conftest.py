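import numpy as np
import pandas as pd
import pytest

from latgrad import data_io
from latgrad import synthetic as syn
from latgrad.phylo import Phylogeny


@pytest.fixture
def three_tip_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tree():
    return Phylogeny.from_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")


@pytest.fixture
def bd_tree_50():
    return syn.simulate_bd_tree(50, 1.0, 0.2, seed=42)


def random_tree(rng, n_tips):
    """Random binary tree with uniform(0.2, 2) branch lengths."""
    tree = syn.simulate_bd_tree(n_tips, 1.0, 0.0,
                                seed=np.random.default_rng(rng.integers(2**31)))
    tree.edge_length[tree.parent >= 0] = rng.uniform(
        0.2, 2.0, int((tree.parent >= 0).sum()))
    return Phylogeny(parent=tree.parent, edge_length=tree.edge_length,
                     labels=tree.labels, n_tips=tree.n_tips)


@pytest.fixture
def trait_table():
    rng = np.random.default_rng(7)
    n = 12
    data = {"species": [f"sp_{i}" for i in range(n)]}
    for c in data_io.TRAIT_COLUMNS:
        data[c] = np.exp(rng.normal(1.0, 0.3, n))
    data["lat_centroid"] = rng.uniform(-60, 60, n)
    return pd.DataFrame(data)
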