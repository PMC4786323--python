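import numpy as np
import pytest

from radpop import SimulationConfig
from radpop.pipeline import run_pipeline

# fixed seeds derived from one pre-registered constant
BASE_SEED = 20160310


@pytest.fixture(scope="session")
def perfect_config():
    """Small error-free scenario where recovery must be exact."""
    return SimulationConfig(
        n_fragments=150,
        mean_depth=70,
        error_rate=0.0,
        missing_rate=0.0,
        low_quality_read_fraction=0.0,
        seed=BASE_SEED + 2,
    )


@pytest.fixture(scope="session")
def perfect_run(perfect_config):
    return run_pipeline(perfect_config)


@pytest.fixture
def rng():
    return np.random.default_rng(BASE_SEED)


def random_additive_tree(n_leaves, rng):
    """A random binary tree with positive branch lengths.

    Used as an oracle: its leaf-to-leaf path lengths form an additive
    metric from which neighbor joining must recover the tree exactly.
    """
    from radpop.popgen import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.uniform(0.5, 2.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(
            children=[nodes[i], nodes[j]], length=float(rng.uniform(0.5, 2.0))
        )
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return root
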