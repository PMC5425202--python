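import numpy as np
import pytest

from fossilplace.parsimony import MISSING
from fossilplace.simulate import random_binary_tree


@pytest.fixture
def quartet():
    from fossilplace.trees import parse_newick

    return parse_newick("((A,B),(C,D));")


def random_character(labels, rng, k=4, p_missing=0.15, p_poly=0.15):
    """One random column over the given leaf labels: single states, some
    polymorphic sets, some MISSING cells."""
    char = {}
    for lab in labels:
        u = rng.random()
        if u < p_missing:
            char[lab] = MISSING
        elif u < p_missing + p_poly:
            size = int(rng.integers(2, k + 1))
            char[lab] = frozenset(
                int(s) for s in rng.choice(k, size=size, replace=False)
            )
        else:
            char[lab] = frozenset([int(rng.integers(k))])
    return char


@pytest.fixture
def rng():
    return np.random.default_rng(20230817)


@pytest.fixture
def random_tree_factory():
    return random_binary_tree
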