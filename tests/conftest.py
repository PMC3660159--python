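import numpy as np
import pytest

from appfam.simulate import SimulationConfig, simulate_family
from appfam.trees import read_newick_string
from appfam.types import AlignedMatrix


@pytest.fixture(scope="session")
def small_bundle():
    """A 3-clade, 9-tip family (plus outgroup) with planted truth."""
    cfg = SimulationConfig(
        n_clades=3, tips_per_clade=3, sequence_length=120, rate=0.25,
        seed=42,
        clade_names=("APL-1", "APPL-1", "APP"),
        domains=[("E2", 30, 70), ("E3", 80, 120)],
        domain_rates={"E2": 1.6, "E3": 0.3},
        planted_synapomorphies={
            "APL-1": [(5, None), (8, None)],
            "APPL-1": [(12, None), (15, None)],
            "APP": [(20, None), (23, None)],
        },
        amyloid_plants=[("*", 95, 12), ("APP", 82, 10)],
        background_weights=None,
    )
    return simulate_family(cfg)


@pytest.fixture
def quartet_matrix():
    return AlignedMatrix(["1", "2", "3", "4"],
                         ["A", "A", "T", "T"], alphabet="nt")


@pytest.fixture
def quartet_tree():
    t = read_newick_string("((1,2),(3,4));")
    t.assign_ids()
    return t


def random_matrix(rng, n_taxa, n_cols, alphabet="ACDE", p_gap=0.05):
    """Small random amino-acid matrix over a reduced alphabet."""
    letters = list(alphabet) + ["-"]
    probs = [(1 - p_gap) / len(alphabet)] * len(alphabet) + [p_gap]
    ids = [f"t{i}" for i in range(n_taxa)]
    rows = ["".join(rng.choice(letters, size=n_cols, p=probs))
            for _ in ids]
    return AlignedMatrix(ids, rows, alphabet="aa")


def random_binary_tree(rng, labels):
    """Random rooted binary tree over the given tip labels."""
    from appfam.trees import Node, PhyloTree
    nodes = [Node(label=l) for l in labels]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    t = PhyloTree(nodes[0])
    t.assign_ids()
    return t
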