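import numpy as np
import pytest
from io import StringIO

from skbio import TreeNode

import mbperm as M


@pytest.fixture
def toy_table():
    """3 taxa x 4 samples (2 subjects, pre/post), proportions."""
    values = np.array(
        [
            [0.5, 0.1, 0.6, 0.2],
            [0.3, 0.7, 0.2, 0.5],
            [0.2, 0.2, 0.2, 0.3],
        ]
    )
    return M.AbundanceTable(
        ["TA", "TB", "TC"], ["s1_pre", "s2_pre", "s1_post", "s2_post"], values,
        mode="proportions",
    )


@pytest.fixture
def toy_design():
    return M.PairedDesign.from_pairs(
        {"s1": ("s1_pre", "s1_post"), "s2": ("s2_pre", "s2_post")}
    )


@pytest.fixture
def sim_default():
    """A default synthetic paired study (8 subjects, 30 taxa)."""
    cfg = M.SimulationConfig(seed=42)
    table, design, truth = M.generate_paired_counts(cfg)
    return cfg, table, design, truth


def tree_from_newick(nwk: str) -> TreeNode:
    return TreeNode.read(StringIO(nwk))


@pytest.fixture
def random_tree16():
    taxa = [f"T{i:03d}" for i in range(16)]
    return taxa, tree_from_newick(M.generate_tree(16, seed=9, taxon_ids=taxa))
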