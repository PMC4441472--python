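import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from selscreen.io import LabeledTree
from selscreen.simulate import SimulationConfig, simulate_alignment

#: A primate-flavored 6-taxon tree; human is the designated foreground.
PRIMATE_TREE = "(((hum#1:0.06,chi:0.06):0.04,rhe:0.1):0.08,(dog:0.15,hor:0.15):0.05,rab:0.2);"

#: Same topology with a long foreground branch (strong-signal scenarios).
LONG_FG_TREE = "(((hum#1:0.25,chi:0.08):0.05,rhe:0.12):0.08,(dog:0.18,hor:0.18):0.06,rab:0.25);"


@pytest.fixture(scope="session")
def primate_tree() -> LabeledTree:
    return LabeledTree.from_newick(PRIMATE_TREE)


@pytest.fixture(scope="session")
def long_fg_tree() -> LabeledTree:
    return LabeledTree.from_newick(LONG_FG_TREE)


@pytest.fixture(scope="session")
def null_alignment(primate_tree):
    """A 300-codon alignment simulated with no positive selection."""
    cfg = SimulationConfig(
        tree_spec=PRIMATE_TREE,
        foreground_branch="hum",
        n_codons=300,
        omega2=1.0,
        site_class_proportions=(0.75, 0.2),
        seed=1234,
    )
    aln, truth = simulate_alignment(cfg)
    return aln, truth


@pytest.fixture(scope="session")
def selected_alignment(long_fg_tree):
    """A 500-codon alignment with a strong foreground signal (omega2 = 8)."""
    cfg = SimulationConfig(
        tree_spec=LONG_FG_TREE,
        foreground_branch="hum",
        n_codons=500,
        omega2=8.0,
        site_class_proportions=(0.65, 0.2),
        seed=7,
    )
    aln, truth = simulate_alignment(cfg)
    return aln, truth
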