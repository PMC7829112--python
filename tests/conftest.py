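import numpy as np
import pytest
from skbio import TreeNode

from gutshift.simulate import make_toy_fixture


@pytest.fixture
def toy():
    """Hand-specified 6x6 fixture whose downstream numbers are documented."""
    return make_toy_fixture()


def random_unrooted_tree(n_taxa: int, rng, low: float = 0.05, high: float = 1.0):
    """Random unrooted binary tree with uniform branch lengths.

    Used as the generating truth for additive-matrix and sequence-
    evolution tests.
    """
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(low, high))
        b.length = float(rng.uniform(low, high))
        parent = TreeNode()
        parent.extend([a, b])
        nodes.append(parent)
    root = TreeNode()
    for nd in nodes:
        nd.length = float(rng.uniform(low, high))
    root.extend(nodes)
    return root


def random_count_table(rng, n_asvs=25, n_samples=8, depth_low=500, depth_high=3000):
    """Random AsvTable with varying depths for property tests."""
    from gutshift.io import AsvTable

    probs = rng.dirichlet(np.full(n_asvs, 0.3))
    cols = []
    for _ in range(n_samples):
        depth = int(rng.integers(depth_low, depth_high))
        cols.append(rng.multinomial(depth, probs))
    return AsvTable(
        [f"ASV{i}" for i in range(n_asvs)],
        [f"S{j}" for j in range(n_samples)],
        np.column_stack(cols),
    )
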