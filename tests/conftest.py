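import numpy as np
import pytest

from zdosage.simulate import SimDesign, simulate_reference


@pytest.fixture(scope="session")
def tiny_design():
    return SimDesign(n_chromosomes=2, genes_per_chromosome=3,
                     timepoints=(0.0, 6.0, 12.0, 18.0), seed=7,
                     protein_length=40)


@pytest.fixture(scope="session")
def tiny_reference(tiny_design):
    return simulate_reference(tiny_design)


@pytest.fixture(scope="session")
def dose_design():
    """1 Z + 4 autosomes x 200 genes, the ratio-analysis workhorse."""
    return SimDesign(n_chromosomes=5, genes_per_chromosome=200,
                     male_fraction=0.5, compensation_failure_factor=2.0,
                     dispersion=0.05, library_size=1e6,
                     timepoints=(48.0,), seed=11, protein_length=30)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with uniform(0.1, 2) branch lengths,
    returned as a zdosage.phylo.Tree. Used to make additive matrices."""
    from zdosage.phylo import Node, Tree

    nodes = [Node(name=f"L{i}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = Node(children=[a, b])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    for nd in nodes:
        nd.length = float(rng.uniform(0.1, 2.0))
    return Tree(Node(children=nodes))
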