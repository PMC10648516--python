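import numpy as np
import pytest

from netseg.netbuild import ConnectivityMatrix
from netseg.partition import SystemPartition, default_partition


@pytest.fixture(scope="session")
def partition120():
    return default_partition()


@pytest.fixture()
def toy_partition():
    """Two systems x two nodes, one of each type."""
    return SystemPartition(
        node_ids=("a1", "a2", "b1", "b2"),
        system_of_node=("A", "A", "B", "B"),
        type_of_system={"A": "association", "B": "sensory-motor"},
    )


@pytest.fixture()
def three_system_partition():
    """Unequal system sizes: A(3) assoc, B(2) assoc, C(2) sensory-motor."""
    return SystemPartition(
        node_ids=tuple(f"n{i}" for i in range(7)),
        system_of_node=("A", "A", "A", "B", "B", "C", "C"),
        type_of_system={
            "A": "association", "B": "association", "C": "sensory-motor",
        },
    )


def make_matrix(values, node_ids):
    return ConnectivityMatrix(values=np.asarray(values, dtype=float),
                              node_ids=tuple(node_ids))


def random_partition(rng, n_nodes):
    """Random partition with 2-4 systems (>= 2 nodes each) and random types."""
    while True:
        n_sys = int(rng.integers(2, 5))
        labels = [f"S{k}" for k in rng.integers(0, n_sys, size=n_nodes)]
        counts = {s: labels.count(s) for s in set(labels)}
        if len(counts) >= 2 and all(c >= 2 for c in counts.values()):
            break
    types = {}
    kinds = ["association", "sensory-motor"]
    for i, s in enumerate(sorted(set(labels))):
        types[s] = kinds[i % 2]
    return SystemPartition(
        node_ids=tuple(f"n{i}" for i in range(n_nodes)),
        system_of_node=tuple(labels),
        type_of_system=types,
    )


def random_zmatrix(rng, n_nodes):
    """Random symmetric nonnegative matrix with zero diagonal."""
    m = rng.random((n_nodes, n_nodes))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m
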