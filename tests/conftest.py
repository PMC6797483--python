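import itertools
import string

import numpy as np
import pytest

from aspen import PrunedTopology, Topology, read_newick


def random_topology(labels, rng) -> Topology:
    """Uniform random rooted binary topology via sequential attachment."""
    labels = list(labels)

    def insert(tr, label, counter):
        if counter[0] == 0:
            counter[0] -= 1
            return (tr, label)
        counter[0] -= 1
        if isinstance(tr, str):
            return tr
        return tuple(insert(c, label, counter) for c in tr)

    def n_nodes(tr):
        return 1 if isinstance(tr, str) else 1 + sum(n_nodes(c) for c in tr)

    tr = (labels[0], labels[1])
    for lab in labels[2:]:
        tr = insert(tr, lab, [int(rng.integers(n_nodes(tr)))])
    return Topology.from_nested(tr)


def labels_for(n: int):
    alpha = string.ascii_uppercase
    if n <= 26:
        return list(alpha[:n])
    return [a + b for a, b in itertools.product(alpha, alpha)][:n]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fig_tree() -> Topology:
    """The six-leaf worked example used throughout the docs."""
    return read_newick("(((A,B),((C,D),E)),F);")


@pytest.fixture
def make_random_topology():
    return random_topology


def as_pruned(t: Topology) -> PrunedTopology:
    return PrunedTopology.from_topology(t)
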