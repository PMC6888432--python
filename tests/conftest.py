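import numpy as np
import pytest

from evoscape.formats_io import MultipleAlignment, PhyloTree
from evoscape.synthetic_data import SimulationConfig, simulate_bundle


@pytest.fixture
def tiny_aln() -> MultipleAlignment:
    return MultipleAlignment(
        taxa=["human", "sp2", "sp3"],
        rows=["M-KT", "MAKT", "MAK-"],
        reference_id="human",
    )


@pytest.fixture
def tiny_tree() -> PhyloTree:
    return PhyloTree.from_newick_string("((human:0.1,sp2:0.2):0.05,sp3:0.3);")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One full synthetic input bundle under the default study conditions."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = simulate_bundle(SimulationConfig(seed=11), outdir)
    return outdir, truth


def random_tree(n_leaves: int, rng: np.random.Generator) -> PhyloTree:
    from evoscape.synthetic_data import simulate_tree

    return simulate_tree(n_leaves, 0.2, rng)
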