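import pytest
from hypothesis import settings

from divkit import synthetic_data, treekit

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_sim():
    """30-leaf tree with 4 phyla, one of them a singleton."""
    return synthetic_data.simulate_tree(
        synthetic_data.TreeSimSpec(
            n_leaves=30, n_phyla=4, n_singleton_phyla=1, seed=7
        )
    )


@pytest.fixture(scope="session")
def small_decorated(small_sim):
    return treekit.decorate(small_sim.tree, small_sim.taxonomy, "phylum")


def path_depths(tree):
    """node_id → root-to-node path length (test-side helper, no library code)."""
    depth = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[nd.node_id] = 0.0
        else:
            depth[nd.node_id] = depth[nd.parent_node.node_id] + (nd.edge.length or 0.0)
    return depth
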