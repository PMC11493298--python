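import numpy as np
import pytest

from structcorr import (
    build_felsenstein_tree,
    parse_newick,
    shared_path_matrix,
    simulate_pure_birth,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def felsenstein_deep():
    """Two 100-tip star clades at divergence 1.0 (tips 0.5) with its vcv."""
    tree = build_felsenstein_tree(100, 0.5, 1.0)
    return tree, shared_path_matrix(tree)


@pytest.fixture
def yule_tree():
    return simulate_pure_birth(50, 1.0, np.random.default_rng(7))
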