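import numpy as np
import pytest

import pipasr as p


@pytest.fixture(scope="session")
def fixture_tree():
    """Six-taxon mammal tree, midpoint-rooted between primates and rodents."""
    return p.mammal_fixture_tree()


@pytest.fixture(scope="session")
def wag():
    return p.wag_model()


@pytest.fixture(scope="session")
def pip_params():
    """Reconstruction parameters matched to the simulator conditions:
    mu = deletion rate 0.1, lambda = mu * root length 1000."""
    return p.PIPParams(lambda_ins=100.0, mu_del=0.1)


@pytest.fixture(scope="session")
def small_replicate(fixture_tree, wag):
    """One simulated replicate at study conditions (root length 1000)."""
    cfg = p.SimulationConfig(seed=1234, model=wag)
    return p.evolve_sequences(fixture_tree, cfg)


def random_tree(rng, n_leaves):
    """Random binary tree with exponential branch lengths, for property tests."""
    nodes = [p.TreeNode(f"L{i}", float(rng.uniform(0.01, 0.5)))
             for i in range(n_leaves)]
    k = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = p.TreeNode(f"I{k}", float(rng.uniform(0.01, 0.5)))
        k += 1
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    root.branch_length = 0.0
    return p.PhyloTree(root)
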