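import numpy as np
import pytest

from wingdiv import biogeography as bg
from wingdiv import synthetic_data as sd
from wingdiv.phylo_core import read_newick


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def two_tip_tree():
    return read_newick("(A:1.0,B:1.0):0.0;")


@pytest.fixture(scope="session")
def yule31():
    """Study-sized pure-birth chronogram shared across modules."""
    return sd.simulate_yule_tree(n_tips=31, lambda0=0.12, seed=11)


@pytest.fixture(scope="session")
def chain3_space():
    """Three areas in a chain A-B-C, ranges up to size 3."""
    adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
    return bg.build_state_space(("A", "B", "C"), adj, 3)


@pytest.fixture(scope="session")
def chain8_space():
    """Eight chain-adjacent areas, ranges up to size 6."""
    adj = np.zeros((8, 8), dtype=bool)
    for i in range(7):
        adj[i, i + 1] = adj[i + 1, i] = True
    return bg.build_state_space(tuple("ABCDEFGH"), adj, 6)
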